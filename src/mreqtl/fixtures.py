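"""Synthetic multi-region expression panel with planted eQTLs.

Generates data shaped like a ten-brain-region expression study: 134
individuals genotyped once (complete dosages, moderate allele frequencies,
LD blocks), overlapping per-region sample subsets of realistic sizes
(CRBL 130 ... SNIG 101), transcript clusters containing multiple exons with
exon-level expression and transcript-level expression summarised as the
winsorised mean of the cluster's exons, and a roster of planted cis/trans,
single-/multi-region eQTLs with known effect sizes.  The planted truth is
what the classification pipeline is validated against.

Planted effects enter at the exon level; transcript-level signal follows
from the summarisation, which is what makes the level classes emerge
naturally: an effect shared by all exons of a cluster appears at both
levels ("both"), an effect confined to one exon of a large cluster is
diluted below transcript-level detectability ("exon-only"), and a weak
effect shared by many exons is individually sub-detectable per exon but
aggregates at the transcript level ("transcript-only").  Because the last
two mechanisms rely on detection thresholds, their expected classes are
probabilistic for borderline plantings; the deterministic truth (SNP,
feature cluster, regions, effect size, cis/trans) always holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from mreqtl.postprocess import ClassifierConfig, classify_cis_trans
from mreqtl.simulation import CHROMOSOMES, simulate_genotypes_ld

#: region roster with per-region sample sizes of the emulated ten-region panel
DEFAULT_REGION_SIZES = {
    "CRBL": 130,
    "FCTX": 127,
    "HIPP": 122,
    "MEDU": 119,
    "OCTX": 129,
    "PUTM": 129,
    "SNIG": 101,
    "TCTX": 119,
    "THAL": 124,
    "WHMT": 131,
}


@dataclass(frozen=True)
class PlantedEqtl:
    """One planted truth entry (effects are per exon, see module docstring)."""

    name: str
    cluster: int
    snp_id: str
    regions: tuple[str, ...]
    beta: float
    cis: bool
    exon_scope: str = "all"  # "all" exons of the cluster, or "one"
    expected_level_class: str = "both"


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and conditions of the synthetic panel."""

    n_individuals: int = 134
    region_sizes: tuple[tuple[str, int], ...] = tuple(DEFAULT_REGION_SIZES.items())
    n_clusters: int = 40
    exons_per_cluster: tuple[int, int] = (3, 6)
    ld_block_size: int = 4
    n_distal_blocks: int = 20
    ld_rho: float = 0.95
    sigma_eps: float = 1.0
    winsor_fraction: float = 0.1
    freq_range: tuple[float, float] = (0.25, 0.75)
    freq_block_jitter: float = 0.03
    roster: Optional[tuple[PlantedEqtl, ...]] = None  # None -> default roster
    seed: int = 0

    def __post_init__(self):
        sizes = dict(self.region_sizes)
        if any(n > self.n_individuals for n in sizes.values()):
            raise ValueError("region sample size exceeds the number of individuals")
        if not (0 <= self.winsor_fraction < 0.5):
            raise ValueError("winsor_fraction must be in [0, 0.5)")
        if self.n_clusters < 1 or self.ld_block_size < 1:
            raise ValueError("n_clusters and ld_block_size must be positive")

    @property
    def n_snp(self) -> int:
        return (self.n_clusters + self.n_distal_blocks) * self.ld_block_size


def winsorised_mean(values, winsor_fraction: float = 0.1) -> float:
    """Classical winsorised mean.

    The ``floor(winsor_fraction * n)`` smallest values are replaced by the
    nearest remaining order statistic, likewise the largest, then the
    arithmetic mean is taken (the convention of
    ``scipy.stats.mstats.winsorize``).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("winsorised_mean of an empty sequence")
    if not (0 <= winsor_fraction < 0.5):
        raise ValueError("winsor_fraction must be in [0, 0.5)")
    from scipy.stats import mstats

    return float(mstats.winsorize(v, limits=(winsor_fraction, winsor_fraction)).mean())


def _winsorise_columns(mat: np.ndarray, frac: float) -> np.ndarray:
    """Row-wise winsorised mean across columns (vectorised order-statistic form)."""
    n = mat.shape[1]
    k = int(np.floor(frac * n))
    if k == 0:
        return mat.mean(axis=1)
    s = np.sort(mat, axis=1)
    s[:, :k] = s[:, [k]]
    s[:, n - k :] = s[:, [n - k - 1]]
    return s.mean(axis=1)


def maf_complete_filter(G: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop SNPs with minor-allele frequency <= 5% or any missing genotype.

    Returns the filtered individuals-by-SNP dosage frame and a report of
    the counts removed at each step.
    """
    n0 = G.shape[1]
    complete = G.columns[G.notna().all(axis=0)]
    G1 = G[complete]
    n_missing = n0 - G1.shape[1]
    freq = G1.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = G1.columns[(maf > 0.05).to_numpy()]
    G2 = G1[keep]
    report = {
        "n_input": n0,
        "n_removed_missing": int(n_missing),
        "n_removed_maf": int(G1.shape[1] - G2.shape[1]),
        "n_retained": int(G2.shape[1]),
    }
    return G2, report


# ---------------------------------------------------------------------------
# genome layout and default roster


def _build_maps(config: FixtureConfig, rng: np.random.Generator):
    """SNP map, annotation table and block/cluster bookkeeping."""
    bs = config.ld_block_size
    snp_rows, block_chrom, block_first = [], [], []
    cluster_chrom, cluster_start = [], []
    for c in range(config.n_clusters):
        chrom = CHROMOSOMES[c % len(CHROMOSOMES)]
        start = 10_000_000 + (c // len(CHROMOSOMES)) * 30_000_000
        cluster_chrom.append(chrom)
        cluster_start.append(start)
        # one cis LD block per cluster, 50 kb upstream of the cluster start
        base = start - 50_000
        block_chrom.append(chrom)
        block_first.append(len(snp_rows))
        for s in range(bs):
            snp_rows.append((f"snp_c{c}_{s}", chrom, base + s * 1_000))
    for d in range(config.n_distal_blocks):
        chrom = CHROMOSOMES[(d * 7 + 3) % len(CHROMOSOMES)]
        base = 150_000_000 + d * 1_000_000
        block_chrom.append(chrom)
        block_first.append(len(snp_rows))
        for s in range(bs):
            snp_rows.append((f"snp_d{d}_{s}", chrom, base + s * 1_000))
    snp_map = pd.DataFrame(snp_rows, columns=["id", "chromosome", "position"])

    lo, hi = config.exons_per_cluster
    n_exons = rng.integers(lo, hi + 1, config.n_clusters)
    ann_rows = []
    exon_ids: list[list[str]] = []
    for c in range(config.n_clusters):
        tc = f"tc{c}"
        ann_rows.append((tc, "transcript", tc, cluster_chrom[c], cluster_start[c],
                         cluster_start[c] + int(n_exons[c]) * 2_000))
        ids = []
        for e in range(int(n_exons[c])):
            ex = f"tc{c}_ex{e}"
            start = cluster_start[c] + e * 2_000
            ann_rows.append((ex, "exon", tc, cluster_chrom[c], start, start + 1_500))
            ids.append(ex)
        exon_ids.append(ids)
    annotation = pd.DataFrame(
        ann_rows,
        columns=["feature_id", "level", "transcript_cluster_id", "chromosome", "start", "end"],
    )
    layout = {
        "snp_map": snp_map,
        "annotation": annotation,
        "cluster_chrom": cluster_chrom,
        "block_first": block_first,
        "block_chrom": block_chrom,
        "exon_ids": exon_ids,
        "n_exons": n_exons,
    }
    return layout


def _distal_snp(layout, config: FixtureConfig, cluster: int, offset: int) -> str:
    """A distal-block SNP on a different chromosome than the given cluster."""
    target = layout["cluster_chrom"][cluster]
    n_blocks = config.n_distal_blocks
    for d in range(offset, offset + n_blocks):
        b = d % n_blocks
        if layout["block_chrom"][config.n_clusters + b] != target:
            return layout["snp_map"]["id"].iloc[
                layout["block_first"][config.n_clusters + b]
            ]
    raise ValueError("no distal block on a different chromosome")


def default_roster(config: FixtureConfig, layout) -> tuple[PlantedEqtl, ...]:
    """The standard planted-truth roster used by the default fixture.

    Mixes all-ten-region cis MR-eQTLs, single-region cis and trans eQTLs,
    cortical-cluster MR-eQTLs, two-region trans MR-eQTLs, exon-only and
    transcript-only plantings.  All entries meant for the |beta| >= 2
    recovery guarantee use effects in [2.2, 3.0].
    """
    regions = [r for r, _ in config.region_sizes]
    all_regions = tuple(regions)

    def cis_snp(cluster):
        return layout["snp_map"]["id"].iloc[layout["block_first"][cluster]]

    roster = []
    for i, beta in enumerate((2.2, 2.5, 2.8, 3.0)):
        roster.append(
            PlantedEqtl(f"mr10_cis_{i}", i, cis_snp(i), all_regions, beta, True)
        )
    for i, region in enumerate(("CRBL", "FCTX", "SNIG")):
        roster.append(
            PlantedEqtl(f"sr_cis_{region}", 4 + i, cis_snp(4 + i), (region,), 2.5, True)
        )
    for i, region in enumerate(("CRBL", "PUTM", "THAL")):
        c = 7 + i
        roster.append(
            PlantedEqtl(
                f"sr_trans_{region}", c, _distal_snp(layout, config, c, i), (region,), 2.6, False
            )
        )
    cortical = ("FCTX", "OCTX", "TCTX")
    for i in range(2):
        c = 10 + i
        roster.append(
            PlantedEqtl(f"mr3_cis_{i}", c, cis_snp(c), cortical, 2.4, True)
        )
    for i, pair in enumerate((("HIPP", "MEDU"), ("OCTX", "WHMT"))):
        c = 12 + i
        roster.append(
            PlantedEqtl(
                f"mr2_trans_{i}", c, _distal_snp(layout, config, c, 5 + i), pair, 2.6, False
            )
        )
    for i, region in enumerate(("OCTX", "WHMT")):
        c = 14 + i
        roster.append(
            PlantedEqtl(
                f"exon_only_{i}", c, cis_snp(c), (region,), 2.2, True,
                exon_scope="one", expected_level_class="exon_only",
            )
        )
    for i, region in enumerate(("MEDU", "TCTX")):
        c = 16 + i
        roster.append(
            PlantedEqtl(
                f"transcript_only_{i}", c, cis_snp(c), (region,), 0.22, True,
                exon_scope="all", expected_level_class="transcript_only",
            )
        )
    return tuple(roster)


#: exon counts forced for clusters carrying dilution-based plantings
_EXON_ONLY_CLUSTER_SIZE = 24
_TRANSCRIPT_ONLY_CLUSTER_SIZE = 20


@dataclass
class FixtureBundle:
    """In-memory synthetic panel plus its planted truth."""

    config: FixtureConfig
    individuals: list[str]
    region_individuals: dict[str, list[str]]
    genotypes: pd.DataFrame
    snp_map: pd.DataFrame
    annotation: pd.DataFrame
    exon_expression: dict[str, pd.DataFrame]
    transcript_expression: dict[str, pd.DataFrame]
    truth: dict

    def write(self, outdir) -> None:
        """Emit the TSV/JSON files consumed by the classification pipeline."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_csv(out / "genotypes.tsv", sep="\t", float_format="%g")
        self.snp_map.to_csv(out / "snp_map.tsv", sep="\t", index=False)
        self.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        expr = out / "expression"
        expr.mkdir(exist_ok=True)
        for region in self.region_individuals:
            self.transcript_expression[region].to_csv(
                expr / f"{region}.transcript.tsv", sep="\t", float_format="%.6g"
            )
            self.exon_expression[region].to_csv(
                expr / f"{region}.exon.tsv", sep="\t", float_format="%.6g"
            )
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def generate_fixture(config: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Generate the synthetic multi-region panel.

    Deterministic for a fixed config/seed (identical files byte for byte).
    Planted cis/trans labels are validated against the generated genomic
    map at generation time.
    """
    config = config or FixtureConfig()
    ss = np.random.SeedSequence(config.seed)
    r_layout, r_geno, r_subset, r_noise = (np.random.default_rng(s) for s in ss.spawn(4))

    layout = _build_maps(config, r_layout)
    roster = config.roster
    if roster is None:
        # dilution-based plantings need large clusters; rewrite the affected
        # clusters' exon counts before drawing the default roster
        forced = {14: _EXON_ONLY_CLUSTER_SIZE, 15: _EXON_ONLY_CLUSTER_SIZE,
                  16: _TRANSCRIPT_ONLY_CLUSTER_SIZE, 17: _TRANSCRIPT_ONLY_CLUSTER_SIZE}
        layout = _rebuild_with_forced_exons(config, layout, forced)
        roster = default_roster(config, layout)

    snp_map = layout["snp_map"]
    annotation = layout["annotation"]
    individuals = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]

    # SNPs of one haplotype block share a base allele frequency (small
    # jitter), as tightly linked variants do; this keeps within-block dosage
    # correlation safely above the R^2 > 0.5 chaining threshold
    n_blocks = config.n_clusters + config.n_distal_blocks
    base = r_geno.uniform(*config.freq_range, n_blocks)
    jitter = r_geno.uniform(
        -config.freq_block_jitter, config.freq_block_jitter, config.n_snp
    )
    freqs = np.clip(
        np.repeat(base, config.ld_block_size) + jitter, 0.05, 0.95
    )
    gm = simulate_genotypes_ld(
        freqs, config.n_individuals, config.ld_block_size, config.ld_rho, r_geno
    )
    genotypes = pd.DataFrame(gm.dosages, index=individuals, columns=snp_map["id"])
    genotypes.index.name = "individual"

    region_individuals = {}
    for region, n in config.region_sizes:
        chosen = sorted(r_subset.choice(individuals, size=n, replace=False))
        region_individuals[region] = chosen

    # planted truth validation against the genomic map
    ann_pos = annotation.set_index("feature_id")
    snp_pos = snp_map.set_index("id")
    cfg_cls = ClassifierConfig()
    for entry in roster:
        tc = f"tc{entry.cluster}"
        label = classify_cis_trans(
            [snp_pos.loc[entry.snp_id, "chromosome"]],
            [snp_pos.loc[entry.snp_id, "position"]],
            [ann_pos.loc[tc, "chromosome"]],
            [ann_pos.loc[tc, "start"]],
            cfg_cls,
        )[0]
        if label != ("cis" if entry.cis else "trans"):
            raise ValueError(f"planted entry {entry.name} violates the cis/trans rule")

    exon_cols = annotation[annotation.level == "exon"]["feature_id"].tolist()
    effects = {region: {} for region in region_individuals}  # exon -> (snp, beta)
    for entry in roster:
        targets = (
            layout["exon_ids"][entry.cluster]
            if entry.exon_scope == "all"
            else layout["exon_ids"][entry.cluster][:1]
        )
        for region in entry.regions:
            for ex in targets:
                effects[region].setdefault(ex, []).append((entry.snp_id, entry.beta))

    exon_expression, transcript_expression = {}, {}
    frac = config.winsor_fraction
    for region, inds in region_individuals.items():
        G = genotypes.loc[inds]
        mat = r_noise.normal(0.0, config.sigma_eps, (len(inds), len(exon_cols)))
        for j, ex in enumerate(exon_cols):
            for snp, beta in effects[region].get(ex, []):
                mat[:, j] += beta * G[snp].to_numpy(dtype=float)
        exon_df = pd.DataFrame(mat, index=inds, columns=exon_cols)
        exon_df.index.name = "individual"
        tr_cols = {}
        for c in range(config.n_clusters):
            ids = layout["exon_ids"][c]
            tr_cols[f"tc{c}"] = _winsorise_columns(exon_df[ids].to_numpy(), frac)
        tr_df = pd.DataFrame(tr_cols, index=inds)
        tr_df.index.name = "individual"
        exon_expression[region] = exon_df
        transcript_expression[region] = tr_df

    truth = {
        "seed": config.seed,
        "regions": {r: len(v) for r, v in region_individuals.items()},
        "planted": [
            {
                "name": e.name,
                "cluster": f"tc{e.cluster}",
                "snp_id": e.snp_id,
                "regions": sorted(e.regions),
                "n_regions": len(e.regions),
                "beta": e.beta,
                "cis_trans": "cis" if e.cis else "trans",
                "exon_scope": e.exon_scope,
                "expected_level_class": e.expected_level_class,
                "expected_sr_mr": "SR" if len(e.regions) == 1 else "MR",
                "strong": abs(e.beta) >= 2,
            }
            for e in roster
        ],
    }
    return FixtureBundle(
        config=config,
        individuals=individuals,
        region_individuals=region_individuals,
        genotypes=genotypes,
        snp_map=snp_map,
        annotation=annotation,
        exon_expression=exon_expression,
        transcript_expression=transcript_expression,
        truth=truth,
    )


def _rebuild_with_forced_exons(config: FixtureConfig, layout, forced: dict[int, int]):
    """Rewrite annotation/exon bookkeeping with forced per-cluster exon counts."""
    n_exons = layout["n_exons"].copy()
    for c, k in forced.items():
        if c < config.n_clusters:
            n_exons[c] = k
    ann = layout["annotation"]
    cluster_start = {
        row.feature_id: row.start
        for row in ann[ann.level == "transcript"].itertuples()
    }
    cluster_chrom = layout["cluster_chrom"]
    rows, exon_ids = [], []
    for c in range(config.n_clusters):
        tc = f"tc{c}"
        start = cluster_start[tc]
        rows.append((tc, "transcript", tc, cluster_chrom[c], start,
                     start + int(n_exons[c]) * 2_000))
        ids = []
        for e in range(int(n_exons[c])):
            ex = f"tc{c}_ex{e}"
            s = start + e * 2_000
            rows.append((ex, "exon", tc, cluster_chrom[c], s, s + 1_500))
            ids.append(ex)
        exon_ids.append(ids)
    new = dict(layout)
    new["annotation"] = pd.DataFrame(
        rows,
        columns=["feature_id", "level", "transcript_cluster_id", "chromosome", "start", "end"],
    )
    new["exon_ids"] = exon_ids
    new["n_exons"] = n_exons
    return new


def score_recovery(bundle: FixtureBundle, outcome) -> pd.DataFrame:
    """Compare a classification outcome against the bundle's planted truth.

    A planted entry is recovered when an eQTL entity exists at the level
    where its effect is visible (the first affected exon for exon-level
    plantings, the transcript for whole-cluster plantings) whose
    representative SNP is linked to the planted SNP at R^2 > 0.5, whose
    region set equals the planted regions exactly, and whose cis/trans
    label matches.  Returns one row per planted entry.
    """
    from mreqtl.postprocess import GenotypePanel

    panel = GenotypePanel(bundle.genotypes)
    ann = bundle.annotation
    ent = outcome.srmr.entities
    rows = []
    for e in bundle.truth["planted"]:
        cluster = e["cluster"]
        if e["exon_scope"] == "one" or e["expected_level_class"] != "transcript_only":
            level = "exon"
            exons = ann[
                (ann.transcript_cluster_id == cluster) & (ann.level == "exon")
            ]["feature_id"]
            feature = exons.iloc[0]
        else:
            level, feature = "transcript", cluster
        cand = ent[(ent.level == level) & (ent.feature_id == feature)]
        recovered = False
        label_ok = regions_ok = False
        for c in cand.itertuples():
            if panel.r2(c.representative_snp, e["snp_id"]) <= 0.5:
                continue
            regions_ok = sorted(c.regions) == e["regions"]
            label_ok = c.cis_trans == e["cis_trans"]
            recovered = regions_ok and label_ok
            if recovered:
                break
        rows.append(
            {
                "name": e["name"],
                "beta": e["beta"],
                "strong": e["strong"],
                "n_regions": e["n_regions"],
                "cis_trans": e["cis_trans"],
                "recovered": recovered,
                "regions_exact": regions_ok,
                "label_correct": label_ok,
            }
        )
    return pd.DataFrame(rows)
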