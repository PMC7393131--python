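"""Quality control and preprocessing of quantified targeted-metabolomics panels.

Works on peak-area tables as exported by triple-quadrupole quantification
software: long format, one row per (metabolite, sample) with cell line,
condition and replicate annotations. Provides the detection/CV filter
applied to LC-MS/MS triplicates, per-sample normalization, treated/control
fold changes with group averaging, and stable-isotope fractional
enrichment from isotopologue areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyPanelError,
    NormalizationError,
    PairingError,
    ValidationError,
)

__all__ = [
    "MetabolitePanel",
    "FoldChangeTable",
    "qc_filter",
    "normalize_samples",
    "fold_change",
    "fractional_enrichment",
]

PANEL_COLUMNS = ["metabolite", "sample", "cell_line", "condition", "replicate", "area"]

#: Replicate group key: the unit at which detection and CV filters apply.
GROUP_KEY = ["metabolite", "cell_line", "condition"]


@dataclass
class MetabolitePanel:
    """Long-format metabolite intensity panel.

    ``data`` has columns (metabolite, sample, cell_line, condition,
    replicate, area); area is an ion count (arbitrary units), NaN = missing.
    """

    data: pd.DataFrame
    normalization: str = "none"

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"panel missing columns: {missing}")
        areas = self.data["area"]
        if (areas.dropna() < 0).any():
            raise ValidationError("intensities must be non-negative or missing")

    @property
    def metabolites(self) -> list:
        return sorted(self.data["metabolite"].unique())

    @property
    def cell_lines(self) -> list:
        return sorted(self.data["cell_line"].unique())

    def line_means(self, condition=None) -> pd.DataFrame:
        """Metabolite x cell-line matrix of replicate-mean intensities."""
        d = self.data
        if condition is not None:
            d = d[d["condition"] == condition]
        return d.pivot_table(index="metabolite", columns="cell_line",
                             values="area", aggfunc="mean")


@dataclass
class FoldChangeTable:
    """Treated/control fold changes per metabolite and cell line.

    ``values`` is a metabolite x cell-line matrix of ratios of replicate
    means; ``group_means`` averages those ratios over declared cell-line
    groups (e.g. radioresistant vs radiosensitive lines).
    """

    values: pd.DataFrame
    group_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    treated_condition: str = ""
    control_condition: str = ""


def _replicate_stats(data: pd.DataFrame) -> pd.DataFrame:
    g = data.groupby(GROUP_KEY)["area"]
    stats = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    stats["cv"] = stats["sd"] / stats["mean"]
    return stats.reset_index()


def qc_filter(panel: MetabolitePanel, min_ion_area: float = 3000.0,
              max_cv: float = 0.5, max_missing_frac: float = 0.5
              ) -> tuple[MetabolitePanel, pd.DataFrame]:
    """Detection-threshold and replicate-CV filter.

    Within each (metabolite, cell_line, condition) replicate group the
    group is set missing when its mean area falls below ``min_ion_area``
    or its coefficient of variation sd/mean (sample sd, ddof=1) exceeds
    ``max_cv``. A metabolite missing in more than ``max_missing_frac`` of
    its groups is dropped entirely. Returns the filtered panel and a QC
    report listing every removal with its reason.
    """
    if min_ion_area < 0:
        raise ConfigurationError("min_ion_area must be >= 0")
    if max_cv <= 0:
        raise ConfigurationError("max_cv must be > 0")
    if panel.data["replicate"].isna().all():
        raise ConfigurationError("replicate annotations are required for QC")

    stats = _replicate_stats(panel.data)
    low = stats["mean"] < min_ion_area
    # Zero-variance groups have CV 0 (or NaN when mean is 0); NaN CV with a
    # detectable mean is treated as passing, since sd of a single replicate
    # is undefined rather than large.
    high_cv = stats["cv"].fillna(0.0) > max_cv
    stats["fail"] = low | high_cv
    stats["reason"] = np.select(
        [low & high_cv, low, high_cv],
        ["low_intensity;high_cv", "low_intensity", "high_cv"],
        default="",
    )

    failed = stats[stats["fail"]][GROUP_KEY + ["mean", "cv", "reason"]]
    data = panel.data.merge(stats[GROUP_KEY + ["fail"]], on=GROUP_KEY, how="left")
    data.loc[data["fail"].fillna(False), "area"] = np.nan
    data = data.drop(columns="fail")

    frac_missing = (
        stats.assign(miss=stats["fail"]).groupby("metabolite")["miss"].mean()
    )
    dropped = frac_missing[frac_missing > max_missing_frac].index
    report_rows = [
        {"metabolite": r.metabolite, "cell_line": r.cell_line,
         "condition": r.condition, "action": "group_masked",
         "reason": r.reason, "mean": r.mean, "cv": r.cv}
        for r in failed.itertuples()
    ]
    report_rows += [
        {"metabolite": m, "cell_line": "", "condition": "",
         "action": "metabolite_dropped",
         "reason": f"missing_fraction>{max_missing_frac}",
         "mean": np.nan, "cv": np.nan}
        for m in dropped
    ]
    data = data[~data["metabolite"].isin(dropped)].reset_index(drop=True)
    if data["metabolite"].nunique() == 0:
        raise EmptyPanelError("QC filtering removed every metabolite")
    report = pd.DataFrame(
        report_rows,
        columns=["metabolite", "cell_line", "condition", "action",
                 "reason", "mean", "cv"],
    )
    return MetabolitePanel(data, normalization=panel.normalization), report


def normalize_samples(panel: MetabolitePanel, method: str = "none",
                      reference_sample=None
                      ) -> tuple[MetabolitePanel, pd.DataFrame]:
    """Divide each sample's intensities by a per-sample factor.

    Methods: ``none`` (identity), ``total_signal`` (factor = sample total
    / mean of totals, so post-normalization totals are equal),
    ``median`` (sample median / mean of medians), ``reference_sample``
    (each sample's factor = median ratio of its intensities to the
    reference sample's, on shared metabolites). Returns the normalized
    panel and a factor table for the QC report.
    """
    if method == "none":
        factors = pd.Series(1.0, index=panel.data["sample"].unique())
    elif method in ("total_signal", "median"):
        agg = "sum" if method == "total_signal" else "median"
        per_sample = panel.data.groupby("sample")["area"].agg(agg)
        if per_sample.isna().any() or (per_sample <= 0).any():
            bad = per_sample.index[(per_sample.isna()) | (per_sample <= 0)][0]
            raise NormalizationError(
                f"non-positive or undefined {method} factor for sample {bad!r}")
        factors = per_sample / per_sample.mean()
    elif method == "reference_sample":
        if reference_sample is None:
            raise ConfigurationError("reference_sample is required for this method")
        wide = panel.data.pivot_table(index="metabolite", columns="sample",
                                      values="area")
        if reference_sample not in wide.columns:
            raise ConfigurationError(f"unknown reference sample {reference_sample!r}")
        ratios = wide.div(wide[reference_sample], axis=0)
        factors = ratios.median(axis=0, skipna=True)
        if factors.isna().any() or (factors <= 0).any():
            bad = factors.index[(factors.isna()) | (factors <= 0)][0]
            raise NormalizationError(f"non-positive factor for sample {bad!r}")
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")

    data = panel.data.copy()
    data["area"] = data["area"] / data["sample"].map(factors).astype(float)
    factor_table = factors.rename("factor").rename_axis("sample").reset_index()
    factor_table.insert(1, "method", method)
    return MetabolitePanel(data, normalization=method), factor_table


def fold_change(panel: MetabolitePanel, treated_condition, control_condition,
                groups: dict | None = None) -> FoldChangeTable:
    """Per-metabolite, per-cell-line treated/control ratio of replicate means.

    ``groups`` maps a group label to the cell lines whose fold changes are
    arithmetically averaged (e.g. resistant vs sensitive line pairs).
    Control means <= 0 yield missing values; a cell line lacking either
    condition raises PairingError.
    """
    treated = panel.line_means(condition=treated_condition)
    control = panel.line_means(condition=control_condition)
    if treated.empty or control.empty:
        raise PairingError(
            f"conditions {treated_condition!r}/{control_condition!r} not both present")
    lines_t, lines_c = set(treated.columns), set(control.columns)
    if lines_t != lines_c:
        raise PairingError(
            f"cell lines lack a matched condition: {sorted(lines_t ^ lines_c)}")
    control = control.reindex(index=treated.index, columns=treated.columns)
    bad_control = control <= 0
    control = control.mask(bad_control)
    values = treated / control
    group_means = pd.DataFrame(index=values.index)
    if groups:
        for label, lines in groups.items():
            missing = [ln for ln in lines if ln not in values.columns]
            if missing:
                raise PairingError(f"group {label!r} references unknown lines {missing}")
            group_means[label] = values[list(lines)].mean(axis=1)
    return FoldChangeTable(values=values, group_means=group_means,
                           treated_condition=str(treated_condition),
                           control_condition=str(control_condition))


def fractional_enrichment(iso: pd.DataFrame) -> pd.Series:
    """Labeled fraction per metabolite from isotopologue peak areas.

    ``iso`` has columns (metabolite, isotopologue_index, area). The
    labeled fraction is the area in isotopologues M+1 and above divided
    by the total isotopologue area. No natural-abundance correction is
    applied: these are raw labeled fractions. A metabolite whose total
    area is zero is reported missing.
    """
    required = {"metabolite", "isotopologue_index", "area"}
    if not required.issubset(iso.columns):
        raise ValidationError(f"isotopologue table needs columns {sorted(required)}")
    if (iso["area"] < 0).any():
        raise ValidationError("isotopologue areas must be non-negative")
    if (iso["isotopologue_index"] < 0).any():
        raise ValidationError("isotopologue indices must be >= 0")
    dup = iso.duplicated(subset=["metabolite", "isotopologue_index"])
    if dup.any():
        raise ValidationError("duplicate isotopologue index within a metabolite")
    has_m0 = iso[iso["isotopologue_index"] == 0]["metabolite"].unique()
    missing_m0 = set(iso["metabolite"]) - set(has_m0)
    if missing_m0:
        raise ValidationError(f"no M+0 record for metabolites {sorted(missing_m0)}")
    total = iso.groupby("metabolite")["area"].sum()
    labeled = iso[iso["isotopologue_index"] >= 1].groupby("metabolite")["area"].sum()
    labeled = labeled.reindex(total.index, fill_value=0.0)
    frac = labeled / total.where(total > 0)
    return frac.rename("labeled_fraction")
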