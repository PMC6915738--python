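"""Sensitivity/specificity scoring of detected vs simulated eQTLs.

Detected associations are compared against the simulation truth over a grid
of absolute effect-size thresholds k: the truth set at threshold k is the
set of simulated eQTL pairs with |beta| >= k, and

    TP = |detected  &  truth-at-k|        FN = |truth-at-k| - TP
    FP = |detected| - TP                  TN = m - TP - FP - FN

so that TP + FP + FN + TN = m always holds.  Note the FP convention: a
detected pair whose true effect lies below k counts as a false positive at
that threshold (the only convention compatible with the identities above);
``confusion_at_threshold(..., exclude_subthreshold_truth=True)`` offers the
alternative reading that removes sub-threshold true pairs from the universe.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); empty denominators
yield NaN, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mreqtl.mapping import MapperConfig, map_eqtls
from mreqtl.simulation import (
    EffectArchitecture,
    SimulationConfig,
    simulate_scenario,
)

DEFAULT_K_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts at one effect-size threshold k."""

    k: float
    TP: int
    FP: int
    FN: int
    TN: int
    m: int

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FP + self.FN + self.TN != self.m:
            raise ValueError("counts must sum to the number of pairs m")


def _as_keys(detected, n_feature: int) -> np.ndarray:
    """Accept flat pair keys or an (snp_idx, feat_idx) pair of arrays."""
    if isinstance(detected, tuple):
        si, fi = (np.asarray(a, dtype=np.int64) for a in detected)
        return si * np.int64(n_feature) + fi
    return np.asarray(detected, dtype=np.int64)


def confusion_at_threshold(
    truth: EffectArchitecture,
    detected,
    k: float,
    m: Optional[int] = None,
    exclude_subthreshold_truth: bool = False,
) -> ConfusionCounts:
    """Score a detected pair set against the simulation truth at threshold k.

    ``detected`` is a set of SNP-feature pairs as flat keys
    (snp_idx * n_trs + feat_idx) or a tuple of index arrays.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    m = truth.n_snp * truth.n_trs if m is None else m
    det = np.unique(_as_keys(detected, truth.n_trs))
    truth_keys = truth.pair_keys()
    at_k = truth.truth_at(k)
    truth_in_det = np.isin(truth_keys, det)
    TP = int((truth_in_det & at_k).sum())
    FN = int(at_k.sum()) - TP
    if exclude_subthreshold_truth:
        below = int((~at_k).sum())
        det_below = int((truth_in_det & ~at_k).sum())
        FP = len(det) - TP - det_below
        m_eff = m - below
        TN = m_eff - TP - FP - FN
        return ConfusionCounts(k, TP, FP, FN, TN, m_eff)
    FP = len(det) - TP
    TN = m - TP - FP - FN
    return ConfusionCounts(k, TP, FP, FN, TN, m)


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity); NaN where the denominator is empty."""
    se = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else float("nan")
    sp = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else float("nan")
    return se, sp


@dataclass
class PerformanceCurve:
    """Replicate-averaged sensitivity/specificity over the k grid."""

    scenario: str
    n_sample: int
    fdr_threshold: float
    k: np.ndarray
    mean_sensitivity: np.ndarray
    mean_specificity: np.ndarray
    se_sensitivity: np.ndarray
    se_specificity: np.ndarray
    n_reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "n_sample": self.n_sample,
                "fdr": self.fdr_threshold,
                "k": self.k,
                "mean_sensitivity": self.mean_sensitivity,
                "mean_specificity": self.mean_specificity,
                "se_sensitivity": self.se_sensitivity,
                "se_specificity": self.se_specificity,
                "n_reps": self.n_reps,
            }
        )


@dataclass
class PowerStudyResult:
    """Per-replicate confusion counts plus aggregation helpers.

    ``counts`` is a long-format frame with one row per
    (scenario, n_sample, fdr, k, replicate): TP, FP, FN, TN, Se, Sp.
    """

    counts: pd.DataFrame
    k_grid: np.ndarray
    n_reps: int

    def curves(self) -> pd.DataFrame:
        g = self.counts.groupby(["scenario", "n_sample", "fdr", "k"], sort=True)
        out = g.agg(
            mean_sensitivity=("Se", "mean"),
            mean_specificity=("Sp", "mean"),
            sd_se=("Se", "std"),
            sd_sp=("Sp", "std"),
            n_reps=("rep", "count"),
        ).reset_index()
        out["se_sensitivity"] = (out.pop("sd_se") / np.sqrt(out["n_reps"])).fillna(0.0)
        out["se_specificity"] = (out.pop("sd_sp") / np.sqrt(out["n_reps"])).fillna(0.0)
        return out

    def curve(self, scenario: str, n_sample: int, fdr: float) -> PerformanceCurve:
        c = self.curves()
        c = c[
            (c.scenario == scenario) & (c.n_sample == n_sample) & (c.fdr == fdr)
        ].sort_values("k")
        if c.empty:
            raise KeyError((scenario, n_sample, fdr))
        return PerformanceCurve(
            scenario,
            n_sample,
            fdr,
            c["k"].to_numpy(),
            c["mean_sensitivity"].to_numpy(),
            c["mean_specificity"].to_numpy(),
            c["se_sensitivity"].to_numpy(),
            c["se_specificity"].to_numpy(),
            int(c["n_reps"].iloc[0]),
        )

    def fdr_summary(self, scenario: str, n_sample: int, k: float) -> pd.DataFrame:
        """FDR-level comparison at one k: mean Se, Sp, FN, FP (Table style)."""
        c = self.counts
        c = c[(c.scenario == scenario) & (c.n_sample == n_sample) & (c.k == k)]
        out = (
            c.groupby("fdr")
            .agg(
                sensitivity=("Se", "mean"),
                specificity=("Sp", "mean"),
                FN=("FN", "mean"),
                FP=("FP", "mean"),
            )
            .reset_index()
        )
        return out

    def undetected_pct(self, scenario: str, n_sample: int, fdr: float) -> float:
        """Mean percentage of all simulated eQTLs (k = 0) not detected."""
        c = self.counts
        c = c[
            (c.scenario == scenario)
            & (c.n_sample == n_sample)
            & (c.fdr == fdr)
            & (c.k == 0.0)
        ]
        return float(100.0 * (1.0 - c["Se"].mean()))

    def scenario_differences(
        self, other_scenario: str, base_scenario: str, n_sample: int, fdr: float
    ) -> pd.DataFrame:
        """Per-k mean Se/Sp differences (other - base) at matched seeds."""
        a = self.curve(other_scenario, n_sample, fdr).to_frame()
        b = self.curve(base_scenario, n_sample, fdr).to_frame()
        out = a[["k"]].copy()
        out["d_sensitivity"] = (
            a["mean_sensitivity"].to_numpy() - b["mean_sensitivity"].to_numpy()
        )
        out["d_specificity"] = (
            a["mean_specificity"].to_numpy() - b["mean_specificity"].to_numpy()
        )
        return out


def _score_replicate(
    arch: EffectArchitecture,
    detected_keys: np.ndarray,
    k_grid: np.ndarray,
    m: int,
) -> pd.DataFrame:
    det = np.unique(detected_keys)
    truth_keys = arch.pair_keys()
    in_det = np.isin(truth_keys, det)
    absb = np.abs(arch.beta)
    rows = []
    D = len(det)
    for k in k_grid:
        at_k = absb >= k
        TP = int((in_det & at_k).sum())
        Tk = int(at_k.sum())
        FN = Tk - TP
        FP = D - TP
        TN = m - TP - FP - FN
        se = TP / Tk if Tk else float("nan")
        sp = TN / (TN + FP) if TN + FP else float("nan")
        rows.append((k, TP, FP, FN, TN, se, sp))
    return pd.DataFrame(rows, columns=["k", "TP", "FP", "FN", "TN", "Se", "Sp"])


def run_scenario(
    scenarios: Sequence[str] | str,
    n_samples: Sequence[int] | int,
    n_reps: int = 10,
    fdr_levels: Sequence[float] = (0.01,),
    k_grid: Optional[np.ndarray] = None,
    base_seed: int = 0,
    mapper_config: Optional[MapperConfig] = None,
    sim_overrides: Optional[dict] = None,
    progress: bool = False,
) -> PowerStudyResult:
    """Sweep scenarios x sample sizes x FDR levels over replicates.

    Replicate r of every grid cell uses seed ``base_seed + r`` (matched seeds
    across scenarios and sample sizes, so paired comparisons are meaningful).
    Simulation parameters other than scenario/sample size can be overridden
    through ``sim_overrides`` (e.g. smaller n_snp/n_trs grids, the effect
    orientation, LD or error-model settings).
    """
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    if isinstance(n_samples, (int, np.integer)):
        n_samples = [int(n_samples)]
    k_grid = DEFAULT_K_GRID if k_grid is None else np.asarray(k_grid, dtype=float)
    fdr_levels = sorted(fdr_levels)
    mcfg = mapper_config or MapperConfig()
    if max(fdr_levels) != mcfg.fdr_threshold:
        mcfg = replace(mcfg, fdr_threshold=max(fdr_levels))
    overrides = dict(sim_overrides or {})

    frames = []
    for scen in scenarios:
        for n in n_samples:
            for rep in range(n_reps):
                cfg = SimulationConfig(
                    scenario=scen, n_sample=n, seed=base_seed + rep, **overrides
                )
                data = simulate_scenario(cfg)
                res = map_eqtls(
                    data.genotypes_analysed.dosages, data.expression.values, mcfg
                )
                for q in fdr_levels:
                    sc = _score_replicate(
                        data.architecture, res.detected_keys(q), k_grid, res.m
                    )
                    sc.insert(0, "rep", rep)
                    sc.insert(0, "fdr", q)
                    sc.insert(0, "n_sample", n)
                    sc.insert(0, "scenario", scen)
                    frames.append(sc)
                if progress:
                    print(f"[run_scenario] {scen} n={n} rep={rep} done", flush=True)
    counts = pd.concat(frames, ignore_index=True)
    return PowerStudyResult(counts=counts, k_grid=k_grid, n_reps=n_reps)


def subsample_eqtl_counts(
    G,
    Y,
    sizes: Sequence[int],
    n_reps: int = 10,
    mapper_config: Optional[MapperConfig] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Detection counts under repeated subsampling of individuals.

    For each requested size, individuals are drawn without replacement
    ``n_reps`` times and the mapper is rerun; per-size counts are sorted
    ascending across replicates, with a median column appended.  Returns the
    table and the full-sample detection count.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = G.shape[0]
    if max(sizes) > n:
        raise ValueError("subsample size exceeds the number of individuals")
    mcfg = mapper_config or MapperConfig()
    full = map_eqtls(G, Y, mcfg).n_detected
    rng = np.random.default_rng(seed)
    rows = {}
    for size in sizes:
        counts = []
        for _ in range(n_reps):
            idx = rng.choice(n, size=size, replace=False)
            counts.append(map_eqtls(G[idx], Y[idx], mcfg).n_detected)
        rows[size] = sorted(counts)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rep_{i+1}" for i in range(n_reps)]
    )
    table.index.name = "n"
    table["median"] = table.median(axis=1)
    return table, full
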