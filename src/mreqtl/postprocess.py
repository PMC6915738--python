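"""From raw association lists to a classified multi-region eQTL catalogue.

The pipeline stages mirror how a multi-region brain expression panel is
analysed in practice:

1. per region and per level (transcript / exon), significant associations
   are collapsed over linkage disequilibrium: SNPs associated with the same
   feature that are adjacent in position order and correlated at R^2 > 0.5
   are chained into one haplotype block represented by its most significant
   SNP;
2. each surviving eQTL is labelled cis- or trans-acting by the distance
   between the SNP and the feature start (10^6.5 bp on the same chromosome;
   different chromosomes are always trans);
3. transcript-level and exon-level lists are combined within transcript
   clusters into transcript-only / exon-only / both classes;
4. records sharing a feature and linked SNPs (R^2 > 0.5) across regions are
   merged into single-region (SR) or multi-region (MR) eQTL entities, from
   which the sharing summaries (pairwise region matrix, regions-count
   frequency table, sharing graph) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

CIS_CUTOFF_BP = 10**6.5  # ~3,162,277.66 bp


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the classification pipeline."""

    r2_threshold: float = 0.5
    cis_cutoff_bp: float = CIS_CUTOFF_BP
    chain_rule: str = "adjacent"  # or "all_pairs"

    def __post_init__(self):
        if self.cis_cutoff_bp <= 0:
            raise ValueError("cis_cutoff_bp must be positive")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.chain_rule not in ("adjacent", "all_pairs"):
            raise ValueError("chain_rule must be 'adjacent' or 'all_pairs'")


class GenotypePanel:
    """Shared genotype panel with cached pairwise dosage R^2.

    Wraps an individuals-by-SNP dosage DataFrame; all regions of a
    multi-region data set reference the same panel, so cross-region R^2 is
    computed on the union of individuals.
    """

    def __init__(self, genotypes: pd.DataFrame):
        self.genotypes = genotypes
        self._cache: dict[tuple[str, str], float] = {}

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        key = (snp_a, snp_b) if snp_a < snp_b else (snp_b, snp_a)
        if key not in self._cache:
            a = self.genotypes[snp_a].to_numpy(dtype=float)
            b = self.genotypes[snp_b].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            self._cache[key] = r * r
        return self._cache[key]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def collapse_redundant(
    records: pd.DataFrame,
    panel: GenotypePanel,
    snp_map: pd.DataFrame,
    config: Optional[ClassifierConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse LD-redundant associations into haplotype blocks.

    Per feature and chromosome, associated SNPs are sorted by position and
    chained while each consecutive pair exceeds R^2 > r2_threshold (strict);
    within a block only the most significant record survives (smallest p,
    ties broken by position then SNP id).  Returns the surviving records
    (with ``block_id`` and ``block_members`` columns) and a block table.
    """
    cfg = config or ClassifierConfig()
    _require_columns(records, ["snp_id", "feature_id", "p"], "association table")
    _require_columns(snp_map, ["id", "chromosome", "position"], "SNP map")
    known = set(snp_map["id"])
    unknown = set(records["snp_id"]) - known
    if unknown:
        raise KeyError(f"SNPs absent from the genotype map: {sorted(unknown)[:5]}")
    pos = snp_map.set_index("id")
    rec = records.copy()
    rec["_chrom"] = pos.loc[rec["snp_id"], "chromosome"].to_numpy()
    rec["_pos"] = pos.loc[rec["snp_id"], "position"].to_numpy()

    surviving, blocks = [], []
    for (feature, chrom), grp in rec.groupby(["feature_id", "_chrom"], sort=True):
        grp = grp.sort_values(["_pos", "snp_id"], kind="stable")
        current: list[int] = []
        member_ids: list[str] = []
        for row in grp.itertuples():
            if not current:
                current, member_ids = [row.Index], [row.snp_id]
                continue
            if cfg.chain_rule == "adjacent":
                linked = panel.r2(member_ids[-1], row.snp_id) > cfg.r2_threshold
            else:
                linked = all(
                    panel.r2(m, row.snp_id) > cfg.r2_threshold for m in member_ids
                )
            if linked:
                current.append(row.Index)
                member_ids.append(row.snp_id)
            else:
                surviving.append(_pick_representative(grp.loc[current]))
                blocks.append((feature, chrom, tuple(member_ids)))
                current, member_ids = [row.Index], [row.snp_id]
        if current:
            surviving.append(_pick_representative(grp.loc[current]))
            blocks.append((feature, chrom, tuple(member_ids)))

    block_table = pd.DataFrame(blocks, columns=["feature_id", "chromosome", "members"])
    block_table["block_id"] = [f"blk{i}" for i in range(len(block_table))]
    out = rec.loc[surviving].drop(columns=["_chrom", "_pos"]).copy()
    out["block_id"] = block_table["block_id"].to_numpy()
    out["block_members"] = block_table["members"].to_numpy()
    block_table["representative"] = out["snp_id"].to_numpy()
    return out.reset_index(drop=True), block_table


def _pick_representative(block_rows: pd.DataFrame) -> int:
    best = block_rows.sort_values(["p", "_pos", "snp_id"], kind="stable")
    return best.index[0]


def classify_cis_trans(
    snp_chrom,
    snp_pos,
    feature_chrom,
    feature_pos,
    config: Optional[ClassifierConfig] = None,
) -> np.ndarray:
    """Label SNP-feature pairs cis or trans by genomic distance.

    Different chromosomes are always trans; on the same chromosome the pair
    is cis iff |snp_pos - feature_pos| < 10^6.5 bp (strict).
    """
    cfg = config or ClassifierConfig()
    snp_chrom = np.asarray(snp_chrom, dtype=object)
    feature_chrom = np.asarray(feature_chrom, dtype=object)
    d = np.abs(np.asarray(snp_pos, dtype=float) - np.asarray(feature_pos, dtype=float))
    cis = (snp_chrom == feature_chrom) & (d < cfg.cis_cutoff_bp)
    return np.where(cis, "cis", "trans")


def annotate_cis_trans(
    records: pd.DataFrame,
    snp_map: pd.DataFrame,
    annotation: pd.DataFrame,
    config: Optional[ClassifierConfig] = None,
) -> pd.DataFrame:
    """Attach chromosome/position columns and the cis/trans label."""
    _require_columns(
        annotation,
        ["feature_id", "level", "transcript_cluster_id", "chromosome", "start"],
        "annotation table",
    )
    ann = annotation.set_index("feature_id")
    missing = set(records["feature_id"]) - set(ann.index)
    if missing:
        raise KeyError(f"features absent from the annotation: {sorted(missing)[:5]}")
    pos = snp_map.set_index("id")
    out = records.copy()
    out["snp_chrom"] = pos.loc[out["snp_id"], "chromosome"].to_numpy()
    out["snp_pos"] = pos.loc[out["snp_id"], "position"].to_numpy()
    out["feature_chrom"] = ann.loc[out["feature_id"], "chromosome"].to_numpy()
    out["feature_start"] = ann.loc[out["feature_id"], "start"].to_numpy()
    out["transcript_cluster_id"] = ann.loc[
        out["feature_id"], "transcript_cluster_id"
    ].to_numpy()
    out["cis_trans"] = classify_cis_trans(
        out["snp_chrom"], out["snp_pos"], out["feature_chrom"], out["feature_start"], config
    )
    return out


def combine_levels(
    transcript_records: pd.DataFrame,
    exon_records: pd.DataFrame,
    annotation: pd.DataFrame,
    panel: GenotypePanel,
    config: Optional[ClassifierConfig] = None,
) -> pd.DataFrame:
    """Combine one region's transcript- and exon-level eQTL lists.

    A transcript-level eQTL with at least one exon-level eQTL of the same
    transcript cluster at the same haplotype (SNPs with R^2 > threshold) is
    labelled ``both`` together with those exon records; a transcript-level
    eQTL with none is ``transcript_only``; exon-level eQTLs in clusters with
    no matching transcript-level eQTL at the same haplotype are
    ``exon_only``.  Returns the concatenated records with ``level`` and
    ``level_class`` columns.
    """
    cfg = config or ClassifierConfig()
    ann = annotation.set_index("feature_id")
    for df, what in ((transcript_records, "transcript"), (exon_records, "exon")):
        missing = set(df["feature_id"]) - set(ann.index)
        if missing:
            raise KeyError(f"unmapped {what} feature ids: {sorted(missing)[:5]}")
    tr = transcript_records.copy()
    ex = exon_records.copy()
    tr["level"] = "transcript"
    ex["level"] = "exon"
    for df in (tr, ex):
        if "transcript_cluster_id" not in df.columns:
            df["transcript_cluster_id"] = ann.loc[
                df["feature_id"], "transcript_cluster_id"
            ].to_numpy()
    tr["level_class"] = "transcript_only"
    ex["level_class"] = "exon_only"
    ex_by_cluster = {c: g for c, g in ex.groupby("transcript_cluster_id")}
    for t in tr.itertuples():
        matches = ex_by_cluster.get(t.transcript_cluster_id)
        if matches is None:
            continue
        linked = [
            e.Index
            for e in matches.itertuples()
            if panel.r2(t.snp_id, e.snp_id) > cfg.r2_threshold
        ]
        if linked:
            tr.loc[t.Index, "level_class"] = "both"
            ex.loc[linked, "level_class"] = "both"
    parts = [df for df in (tr, ex) if not df.empty]
    if not parts:
        return tr.iloc[0:0]
    return pd.concat(parts, ignore_index=True)


@dataclass
class SrMrResult:
    """Catalogue of SR/MR eQTL entities with sharing summaries."""

    records: pd.DataFrame  # per-region records with eqtl_id
    entities: pd.DataFrame  # one row per merged eQTL entity

    def region_totals(self, level: Optional[str] = None) -> pd.DataFrame:
        """Per-region eQTL counts split cis/trans."""
        rec = self.records if level is None else self.records[self.records.level == level]
        out = (
            rec.groupby(["region", "cis_trans"]).size().unstack(fill_value=0)
        )
        for col in ("cis", "trans"):
            if col not in out.columns:
                out[col] = 0
        out["total"] = out["cis"] + out["trans"]
        return out[["cis", "trans", "total"]]

    def sr_totals(self, level: Optional[str] = None) -> pd.DataFrame:
        """Per-region single-region eQTL counts split cis/trans."""
        ent = self.entities[self.entities.n_regions == 1]
        if level is not None:
            ent = ent[ent.level == level]
        rows = []
        for e in ent.itertuples():
            rows.append((next(iter(e.regions)), e.cis_trans))
        df = pd.DataFrame(rows, columns=["region", "cis_trans"])
        if df.empty:
            return pd.DataFrame(columns=["cis", "trans", "total"])
        out = df.groupby(["region", "cis_trans"]).size().unstack(fill_value=0)
        for col in ("cis", "trans"):
            if col not in out.columns:
                out[col] = 0
        out["total"] = out["cis"] + out["trans"]
        return out[["cis", "trans", "total"]]

    def frequency_table(self, level: str) -> pd.DataFrame:
        """Regions-count frequency table with cumulative eQTL counts.

        An MR entity present in r regions contributes r eQTLs to the
        cumulative column, so sum(r * frequency) equals the total number of
        per-region eQTL records.
        """
        ent = self.entities[self.entities.level == level]
        freq = ent.groupby("n_regions").size()
        out = pd.DataFrame(
            {
                "n_regions": freq.index.to_numpy(),
                "frequency": freq.to_numpy(),
            }
        )
        out["cumulative_eqtls"] = out["n_regions"] * out["frequency"]
        return out.reset_index(drop=True)

    def sharing_matrix(self, level: str) -> pd.DataFrame:
        """Symmetric region-by-region matrix of shared MR-eQTL counts."""
        ent = self.entities[self.entities.level == level]
        regions = sorted(self.records["region"].unique())
        mat = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
        for e in ent.itertuples():
            rs = sorted(e.regions)
            if len(rs) < 2:
                continue
            for i, a in enumerate(rs):
                for b in rs[i + 1 :]:
                    mat.loc[a, b] += 1
                    mat.loc[b, a] += 1
        return mat

    def sharing_graph(self) -> dict:
        """JSON-serialisable region-sharing graph (nodes + cis/trans edges)."""
        nodes = []
        totals = self.region_totals()
        for region in totals.index:
            nodes.append(
                {
                    "region": region,
                    "n_eqtl": int(totals.loc[region, "total"]),
                    "n_cis": int(totals.loc[region, "cis"]),
                    "n_trans": int(totals.loc[region, "trans"]),
                }
            )
        edges: dict[tuple[str, str], dict] = {}
        for e in self.entities.itertuples():
            rs = sorted(e.regions)
            for i, a in enumerate(rs):
                for b in rs[i + 1 :]:
                    d = edges.setdefault(
                        (a, b), {"region_a": a, "region_b": b, "shared": 0, "shared_cis": 0, "shared_trans": 0}
                    )
                    d["shared"] += 1
                    d["shared_cis" if e.cis_trans == "cis" else "shared_trans"] += 1
        return {"nodes": nodes, "edges": sorted(edges.values(), key=lambda d: (d["region_a"], d["region_b"]))}


def identify_sr_mr(
    records: pd.DataFrame,
    panel: GenotypePanel,
    config: Optional[ClassifierConfig] = None,
) -> SrMrResult:
    """Merge per-region records into SR/MR eQTL entities.

    Records (across regions) with the same feature id and SNPs correlated at
    R^2 > threshold are considered the same eQTL acting in the union of
    their regions.  Merging is by connected components of the R^2 linkage
    graph within each (level, feature) group.
    """
    cfg = config or ClassifierConfig()
    _require_columns(
        records, ["region", "level", "feature_id", "snp_id", "p", "cis_trans"], "records"
    )
    rec = records.copy().reset_index(drop=True)
    rec["eqtl_id"] = ""
    entities = []
    next_id = 0
    for (level, feature), grp in rec.groupby(["level", "feature_id"], sort=True):
        idx = list(grp.index)
        parent = {i: i for i in idx}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1 :]:
                if panel.r2(rec.at[a, "snp_id"], rec.at[b, "snp_id"]) > cfg.r2_threshold:
                    parent[find(a)] = find(b)
        comps: dict[int, list[int]] = {}
        for i in idx:
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            sub = rec.loc[members].sort_values(["p", "snp_id"], kind="stable")
            eid = f"eqtl{next_id}"
            next_id += 1
            rec.loc[members, "eqtl_id"] = eid
            regions = frozenset(sub["region"])
            entities.append(
                {
                    "eqtl_id": eid,
                    "level": level,
                    "feature_id": feature,
                    "representative_snp": sub["snp_id"].iloc[0],
                    "regions": regions,
                    "n_regions": len(regions),
                    "sr_mr": "SR" if len(regions) == 1 else "MR",
                    # label of the most significant member; members of one
                    # entity virtually always agree
                    "cis_trans": sub["cis_trans"].iloc[0],
                    "mean_abs_beta": float(np.abs(sub["beta"]).mean())
                    if "beta" in sub
                    else np.nan,
                }
            )
    entity_cols = [
        "eqtl_id",
        "level",
        "feature_id",
        "representative_snp",
        "regions",
        "n_regions",
        "sr_mr",
        "cis_trans",
        "mean_abs_beta",
    ]
    return SrMrResult(records=rec, entities=pd.DataFrame(entities, columns=entity_cols))


_BINS = ((1, 1, "1"), (2, 5, "2-5"), (6, 10, "6-10"), (11, np.inf, ">10"))


def bin_frequencies(records: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Binned multiplicity table (1, 2-5, 6-10, >10 plus a Max column).

    ``axis="features_per_haplotype"`` counts, per region and level, how many
    distinct features each haplotype (representative SNP) is associated
    with; ``axis="haplotypes_per_feature"`` counts haplotypes per feature.
    """
    if axis == "features_per_haplotype":
        unit, counted = "snp_id", "feature_id"
    elif axis == "haplotypes_per_feature":
        unit, counted = "feature_id", "snp_id"
    else:
        raise ValueError("axis must be 'features_per_haplotype' or 'haplotypes_per_feature'")
    cols = [f"bin_{label}" for _, _, label in _BINS] + ["max"]
    if records.empty:
        return pd.DataFrame(columns=["region", "level"] + cols)
    mult = (
        records.groupby(["region", "level", unit])[counted]
        .nunique()
        .rename("multiplicity")
        .reset_index()
    )
    rows = []
    for (region, level), grp in mult.groupby(["region", "level"], sort=True):
        m = grp["multiplicity"]
        row = {"region": region, "level": level}
        for lo, hi, label in _BINS:
            row[f"bin_{label}"] = int(((m >= lo) & (m <= hi)).sum())
        row["max"] = int(m.max())
        rows.append(row)
    return pd.DataFrame(rows, columns=["region", "level"] + cols)


# ---------------------------------------------------------------------------
# end-to-end classification workflow


@dataclass
class ClassificationOutcome:
    """Everything the classification pipeline produces."""

    catalogue: pd.DataFrame  # per-region collapsed, labelled records
    srmr: SrMrResult
    region_totals: pd.DataFrame
    sr_totals: pd.DataFrame
    frequency_tables: dict
    sharing_matrices: dict
    bins_features_per_haplotype: pd.DataFrame
    bins_haplotypes_per_feature: pd.DataFrame
    sharing_graph: dict


def classify_regions(
    genotypes: pd.DataFrame,
    snp_map: pd.DataFrame,
    annotation: pd.DataFrame,
    expression: dict,
    mapper_config=None,
    config: Optional[ClassifierConfig] = None,
) -> ClassificationOutcome:
    """Run the full per-region mapping and classification pipeline.

    ``expression`` maps (region, level) -> individuals-by-feature DataFrame;
    every region's individuals must be rows of ``genotypes``.  Each region
    and level is mapped separately (BH-FDR within that mapping), collapsed
    over LD, labelled cis/trans, combined across levels within the region,
    and finally merged across regions into SR/MR entities.
    """
    from mreqtl.mapping import MapperConfig, map_eqtls

    cfg = config or ClassifierConfig()
    mcfg = mapper_config or MapperConfig()
    panel = GenotypePanel(genotypes)
    regions = sorted({r for r, _ in expression})
    per_region = []
    for region in regions:
        per_level = {}
        for level in ("transcript", "exon"):
            if (region, level) not in expression:
                raise ValueError(f"missing expression table for {region}/{level}")
            expr = expression[(region, level)]
            missing = set(expr.index) - set(genotypes.index)
            if missing:
                raise ValueError(
                    f"individuals in {region}/{level} absent from genotypes: "
                    f"{sorted(missing)[:5]}"
                )
            G = genotypes.loc[expr.index]
            res = map_eqtls(G, expr, mcfg)
            hits = res.records[res.records.detected].copy()
            collapsed, _ = collapse_redundant(hits, panel, snp_map, cfg)
            per_level[level] = annotate_cis_trans(collapsed, snp_map, annotation, cfg)
        combined = combine_levels(
            per_level["transcript"], per_level["exon"], annotation, panel, cfg
        )
        combined.insert(0, "region", region)
        per_region.append(combined)
    catalogue = pd.concat(per_region, ignore_index=True)
    srmr = identify_sr_mr(catalogue, panel, cfg)
    freq_tables = {lvl: srmr.frequency_table(lvl) for lvl in ("transcript", "exon")}
    share = {lvl: srmr.sharing_matrix(lvl) for lvl in ("transcript", "exon")}
    return ClassificationOutcome(
        catalogue=srmr.records,
        srmr=srmr,
        region_totals=srmr.region_totals(),
        sr_totals=srmr.sr_totals(),
        frequency_tables=freq_tables,
        sharing_matrices=share,
        bins_features_per_haplotype=bin_frequencies(
            srmr.records, "features_per_haplotype"
        ),
        bins_haplotypes_per_feature=bin_frequencies(
            srmr.records, "haplotypes_per_feature"
        ),
        sharing_graph=srmr.sharing_graph(),
    )
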