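"""Pathway regulation scoring and its correlation with radiosensitivity.

The discovery computation of the pipeline. Metabolite levels measured
across a panel of cell lines are z-transformed (zero mean, unit variance
across lines), metabolites with z below -1 are called downregulated and
above +1 upregulated, and each pathway in each line receives a down- and
an up-regulation score: the fraction of the pathway's measured
metabolites carrying that call. The per-pathway score vectors are then
Pearson-correlated with the panel's radiosensitivity — the negated mean
inactivating dose (-Dmid), so positive r means "more downregulated in
more radiosensitive lines" — with two-sided t-distribution p-values and
Benjamini-Hochberg q-values across pathways.

A post-irradiation variant applies the same machinery to log2 fold
changes of matched irradiated/unirradiated samples, and additionally
reports group-averaged fold changes for declared line groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import (
    ConfigurationError,
    SampleSizeError,
    ValidationError,
)
from .msprep import FoldChangeTable, MetabolitePanel
from .stats_core import bh_fdr, pearson_r_p

__all__ = [
    "ZMatrix",
    "RegulationCalls",
    "PathwayScores",
    "ResistanceScore",
    "z_transform",
    "regulation_calls",
    "pathway_scores",
    "correlate_pathways",
    "post_rt_pathway_analysis",
]


@dataclass
class ZMatrix:
    """Row-standardized metabolite x analysis-unit matrix.

    Retained rows have mean 0 and sample sd 1 (ddof=1) over their
    non-missing entries; zero-variance metabolites are listed in
    ``dropped`` rather than emitted as z = 0. ``n_effective`` records the
    number of non-missing units per metabolite (pairwise-complete
    standardization).
    """

    z: pd.DataFrame
    dropped: list = field(default_factory=list)
    n_effective: pd.Series = field(default_factory=pd.Series)


@dataclass
class RegulationCalls:
    """Per-metabolite, per-unit regulation calls: -1 down, 0 none, +1 up."""

    calls: pd.DataFrame
    z_lower: float
    z_upper: float

    def counts(self) -> pd.DataFrame:
        """Up/down/none counts per analysis unit (column)."""
        return pd.DataFrame({
            "down": (self.calls == -1).sum(),
            "none": (self.calls == 0).sum(),
            "up": (self.calls == 1).sum(),
        })


@dataclass
class PathwayScores:
    """Fraction of each pathway's measured metabolites called down/up.

    ``down`` and ``up`` are pathway x unit matrices with entries in
    [0, 1]; ``n_measured`` counts the non-missing metabolites behind each
    entry. down + up <= 1 elementwise.
    """

    down: pd.DataFrame
    up: pd.DataFrame
    n_measured: pd.DataFrame
    unmapped: list = field(default_factory=list)


@dataclass
class ResistanceScore:
    """Per-unit radioresistance (Dmid, Gy); sensitivity is its negation.

    The correlation analysis is reported against the sensitivity
    orientation (-Dmid), so that positive correlation of a down-score
    means the pathway is depleted in radiosensitive lines.
    """

    dmid: pd.Series
    orientation: str = "sensitivity"

    def __post_init__(self) -> None:
        if (self.dmid <= 0).any():
            raise ValidationError("Dmid values must be positive")
        if self.orientation not in ("sensitivity", "resistance"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def values(self) -> pd.Series:
        return -self.dmid if self.orientation == "sensitivity" else self.dmid


def _as_matrix(data) -> pd.DataFrame:
    if isinstance(data, MetabolitePanel):
        return data.line_means()
    if isinstance(data, FoldChangeTable):
        return data.values
    if isinstance(data, pd.DataFrame):
        return data
    raise ValidationError(f"cannot standardize object of type {type(data).__name__}")


def z_transform(data, min_units: int = 3) -> ZMatrix:
    """Standardize each metabolite across analysis units (columns).

    z = (x - mean) / sd with the sample standard deviation (ddof=1),
    computed over non-missing entries. Rows with zero variance (or fewer
    than two observations) are moved to ``dropped``.
    """
    mat = _as_matrix(data)
    if mat.shape[1] < min_units:
        raise SampleSizeError(
            f"need >= {min_units} analysis units, got {mat.shape[1]}")
    values = mat.to_numpy(dtype=float)
    n_eff = np.sum(np.isfinite(values), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
        sd = np.nanstd(np.where(np.isfinite(values), values, np.nan),
                       axis=1, ddof=1)
    ok = (n_eff >= 2) & (sd > 0)
    z = (values - mean[:, None]) / np.where(ok, sd, np.nan)[:, None]
    zdf = pd.DataFrame(z[ok], index=mat.index[ok], columns=mat.columns)
    dropped = list(mat.index[~ok])
    return ZMatrix(z=zdf, dropped=dropped,
                   n_effective=pd.Series(n_eff[ok], index=mat.index[ok]))


def regulation_calls(zmat: ZMatrix, z_lower: float = -1.0,
                     z_upper: float = 1.0) -> RegulationCalls:
    """Call metabolites down (z strictly below z_lower) or up (strictly above
    z_upper); boundary values are "none"."""
    if z_lower >= z_upper:
        raise ConfigurationError("z_lower must be strictly below z_upper")
    z = zmat.z.to_numpy(dtype=float)
    calls = np.where(z < z_lower, -1.0, np.where(z > z_upper, 1.0, 0.0))
    calls = np.where(np.isfinite(z), calls, np.nan)
    return RegulationCalls(
        calls=pd.DataFrame(calls, index=zmat.z.index, columns=zmat.z.columns),
        z_lower=z_lower, z_upper=z_upper)


def _pathway_map_series(pathway_map) -> pd.Series:
    if isinstance(pathway_map, pd.DataFrame):
        required = {"metabolite", "pathway"}
        if not required.issubset(pathway_map.columns):
            raise ValidationError("pathway map needs columns (metabolite, pathway)")
        dup = pathway_map["metabolite"].duplicated()
        if dup.any():
            bad = pathway_map.loc[dup, "metabolite"].iloc[0]
            raise ValidationError(
                f"metabolite {bad!r} mapped to more than one pathway")
        return pathway_map.set_index("metabolite")["pathway"]
    s = pd.Series(pathway_map)
    if s.index.duplicated().any():
        raise ValidationError("metabolite mapped to more than one pathway")
    return s


def pathway_scores(calls: RegulationCalls, pathway_map) -> PathwayScores:
    """Per (pathway, unit) down/up score: #calls / #measured metabolites.

    Metabolites absent from the map are excluded (and listed in
    ``unmapped``); pathways with no measured metabolite in any unit are
    excluded entirely.
    """
    mapping = _pathway_map_series(pathway_map)
    measured = calls.calls.index
    unmapped = [m for m in measured if m not in mapping.index]
    kept = [m for m in measured if m in mapping.index]
    if not kept:
        raise ValidationError("no measured metabolite maps to any pathway")
    sub = calls.calls.loc[kept]
    groups = mapping.loc[kept]
    n_measured = sub.notna().groupby(groups).sum()
    down = (sub == -1).groupby(groups).sum()
    up = (sub == 1).groupby(groups).sum()
    nonempty = n_measured.sum(axis=1) > 0
    n_measured = n_measured[nonempty]
    denominator = n_measured.where(n_measured > 0)
    return PathwayScores(
        down=(down[nonempty] / denominator),
        up=(up[nonempty] / denominator),
        n_measured=n_measured,
        unmapped=unmapped,
    )


def correlate_pathways(scores: PathwayScores, resistance: ResistanceScore,
                       direction: str = "down",
                       fdr_threshold: float = 0.1,
                       p_threshold: float = 0.05) -> pd.DataFrame:
    """Pearson-correlate per-pathway scores with the sensitivity score.

    Returns one row per pathway: (pathway, direction, n, r, p, q,
    significant). q-values are Benjamini-Hochberg across the pathways
    actually tested in this direction (one family per direction);
    zero-variance or under-sampled pathways carry missing r and are not
    counted in the family. ``significant`` requires both p < p_threshold
    and q < fdr_threshold.
    """
    if direction not in ("down", "up"):
        raise ValidationError(f"direction must be 'down' or 'up', not {direction!r}")
    mat = scores.down if direction == "down" else scores.up
    shared = [u for u in mat.columns if u in resistance.dmid.index]
    if len(shared) < 3:
        raise SampleSizeError(
            "need >= 3 shared analysis units between scores and resistance")
    if len(shared) < len(mat.columns) or len(shared) < len(resistance.dmid):
        missing = sorted(set(mat.columns) ^ set(resistance.dmid.index))
        if set(mat.columns) != set(resistance.dmid.index):
            raise ValidationError(
                f"cell-line sets differ between scores and resistance: {missing}")
    y_full = resistance.values.loc[shared]
    rows = []
    for pathway, score_vec in mat[shared].iterrows():
        ok = score_vec.notna() & y_full.notna()
        x = score_vec[ok].to_numpy(dtype=float)
        y = y_full[ok].to_numpy(dtype=float)
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"pathway": pathway, "direction": direction,
                         "n": int(x.size), "r": np.nan, "p": np.nan})
            continue
        res = pearson_r_p(x, y)
        rows.append({"pathway": pathway, "direction": direction,
                     "n": res.n, "r": res.effect, "p": res.p_value})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = (out["p"] < p_threshold) & (out["q"] < fdr_threshold)
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def post_rt_pathway_analysis(fc: FoldChangeTable, resistance: ResistanceScore,
                             pathway_map, config: RunConfig | None = None
                             ) -> tuple[pd.DataFrame, PathwayScores, pd.DataFrame]:
    """Pathway analysis of post-irradiation fold changes.

    log2 fold changes are standardized across analysis units, regulation
    is called at the configured thresholds, pathway scores are formed and
    correlated with the sensitivity score for both directions. Returns
    (correlation table, scores, group-mean fold-change table).
    """
    config = config or RunConfig()
    values = fc.values
    if (values.dropna(how="all").stack() <= 0).any():
        raise ValidationError("fold changes must be positive to log-transform")
    logfc = np.log2(values)
    zmat = z_transform(logfc)
    if zmat.z.empty:
        return (pd.DataFrame(columns=["pathway", "direction", "n", "r", "p",
                                      "q", "significant"]),
                PathwayScores(down=pd.DataFrame(), up=pd.DataFrame(),
                              n_measured=pd.DataFrame()),
                fc.group_means)
    calls = regulation_calls(zmat, config.z_lower, config.z_upper)
    scores = pathway_scores(calls, pathway_map)
    tables = [
        correlate_pathways(scores, resistance, direction=direction,
                           fdr_threshold=config.fdr_threshold,
                           p_threshold=config.p_threshold)
        for direction in ("down", "up")
    ]
    return pd.concat(tables, ignore_index=True), scores, fc.group_means
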