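"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and its
output validates against the same schemas the readers enforce. The
defaults emulate the study designs this pipeline targets: a 23-cell-line
metabolite panel whose guanylate pathway is coupled to a latent
radioresistance score, Poisson colony counts from linear-quadratic
survival at doses 0-8 Gy, exponential flank-tumor growth with
multiplicative treatment effects measured three times weekly, and
exponential survival with a group hazard ratio and administrative
censoring.

Panel coupling model: per-line Dmid is drawn uniformly over a Gy range
and standardized to z_D. Each metabolite of the coupled pathway receives
per-line mean r_true * z_D + sqrt(1 - r_true^2) * eps with independent
unit-normal eps, so every coupled metabolite's population correlation
with Dmid is r_true (the pathway mean's correlation is then higher,
since independent metabolite noise averages out). Per-replicate
lognormal measurement noise attenuates realized estimates slightly, as
it does in real panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .invivo_endpoints import GrowthSeries
from .msprep import MetabolitePanel
from .pathway_corr import ResistanceScore

__all__ = [
    "SyntheticTruth",
    "default_pathway_sizes",
    "default_pathway_map",
    "simulate_metabolite_panel",
    "simulate_clonogenic_assay",
    "simulate_growth_cohort",
    "simulate_survival_cohort",
]

#: Pathway panel used by default: purine/pyrimidine and redox families with
#: a handful of synthetic metabolites each.
DEFAULT_PATHWAY_SIZES = {
    "guanylates": 6,
    "adenylates": 6,
    "inosinates": 3,
    "cytidine": 4,
    "glutathione": 5,
    "nucleotide_sugar": 4,
}

DEFAULT_DMID_RANGE = (1.5, 5.5)  # Gy; spans sensitive to resistant lines


@dataclass
class SyntheticTruth:
    """Generating parameters recorded alongside every synthetic dataset."""

    seed: int
    panel: dict = field(default_factory=dict)
    clonogenic: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def default_pathway_sizes() -> dict:
    return dict(DEFAULT_PATHWAY_SIZES)


def default_pathway_map(pathways: dict | None = None) -> pd.DataFrame:
    """Metabolite -> pathway table for the synthetic panel."""
    pathways = pathways or DEFAULT_PATHWAY_SIZES
    rows = [
        {"metabolite": f"{pw}_m{i + 1}", "pathway": pw}
        for pw, size in pathways.items()
        for i in range(size)
    ]
    return pd.DataFrame(rows)


def simulate_metabolite_panel(
    n_lines: int = 23,
    pathways: dict | None = None,
    coupled_pathway: str = "guanylates",
    r_true: float = 0.8,
    noise_sd: float = 0.25,
    line_sd: float = 0.4,
    replicates: int = 3,
    seed: int = 0,
    dmid_range: tuple = DEFAULT_DMID_RANGE,
    base_log_intensity: float = np.log(1e5),
) -> tuple[MetabolitePanel, ResistanceScore, SyntheticTruth]:
    """Metabolite panel with one pathway coupled to radioresistance.

    All non-coupled metabolites are independent unit-normal noise on the
    log scale; replicate measurements add lognormal noise of sd
    ``noise_sd``. ``line_sd`` scales the between-line structure on the
    log scale (the default 0.4 corresponds to a ~50% between-line CV of
    intensities, keeping the intensity distribution close enough to
    symmetric that both tails of the z distribution are populated).
    ``r_true = 0`` produces a global-null panel.
    """
    if n_lines < 3:
        raise ConfigurationError("need >= 3 cell lines")
    pathways = pathways or DEFAULT_PATHWAY_SIZES
    if any(size < 1 for size in pathways.values()):
        raise ConfigurationError("pathway sizes must be >= 1")
    if coupled_pathway is not None and coupled_pathway not in pathways:
        raise ConfigurationError(
            f"coupled pathway {coupled_pathway!r} not in the pathway map")
    if not -1.0 < r_true < 1.0:
        raise ConfigurationError("r_true must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]
    dmid = rng.uniform(*dmid_range, size=n_lines)
    z_d = (dmid - dmid.mean()) / dmid.std(ddof=1)

    records = []
    for pw, size in pathways.items():
        if coupled_pathway is not None and pw == coupled_pathway:
            # Each coupled metabolite correlates with Dmid at r_true.
            eps = rng.standard_normal((size, n_lines))
            means = r_true * z_d[None, :] + np.sqrt(1.0 - r_true**2) * eps
        else:
            means = rng.standard_normal((size, n_lines))
        rep_noise = rng.normal(0.0, noise_sd, size=(size, n_lines, replicates))
        log_intensity = (base_log_intensity + line_sd * means[:, :, None]
                         + rep_noise)
        for i in range(size):
            met = f"{pw}_m{i + 1}"
            for j, line in enumerate(lines):
                for r in range(replicates):
                    records.append({
                        "metabolite": met,
                        "sample": f"{line}_baseline_r{r + 1}",
                        "cell_line": line,
                        "condition": "baseline",
                        "replicate": r + 1,
                        "area": float(np.exp(log_intensity[i, j, r])),
                    })
    panel = MetabolitePanel(pd.DataFrame(records))
    resistance = ResistanceScore(pd.Series(dmid, index=lines, name="dmid"))
    truth = SyntheticTruth(seed=seed, panel={
        "coupled_pathway": coupled_pathway, "r_true": r_true,
        "noise_sd": noise_sd, "line_sd": line_sd,
        "dmid": dict(zip(lines, map(float, dmid))),
        "n_lines": n_lines, "replicates": replicates,
        "pathways": dict(pathways),
    })
    return panel, resistance, truth


def simulate_clonogenic_assay(
    alpha: float = 0.2,
    beta: float = 0.05,
    pe: float = 0.5,
    cells_plated: int = 500,
    doses=(0.0, 2.0, 4.0, 6.0, 8.0),
    replicates: int = 3,
    seed: int = 0,
    cell_line: str = "synthetic",
    treatment: str = "control",
) -> pd.DataFrame:
    """Poisson colony counts from linear-quadratic survival.

    colonies ~ Poisson(cells_plated * pe * exp(-(alpha d + beta d^2)))
    per replicate, truncated at cells_plated (a colony needs a plated cell).
    """
    doses = np.asarray(doses, dtype=float)
    if not (0.0 < pe <= 1.0):
        raise ConfigurationError("plating efficiency must lie in (0, 1]")
    if 0.0 not in doses:
        raise ConfigurationError("dose schedule must include 0 Gy")
    if alpha < 0 or beta < 0:
        raise ConfigurationError("alpha and beta must be non-negative")
    expected = cells_plated * pe * np.exp(-(alpha * doses + beta * doses**2))
    if np.any(expected > cells_plated):
        raise ConfigurationError("expected colonies exceed cells plated")
    rng = np.random.default_rng(seed)
    rows = []
    for d, mu in zip(doses, expected):
        counts = np.minimum(rng.poisson(mu, size=replicates), cells_plated)
        for r, c in enumerate(counts, start=1):
            rows.append({"cell_line": cell_line, "treatment": treatment,
                         "dose_gy": float(d), "cells_plated": int(cells_plated),
                         "colonies": int(c), "replicate": r})
    return pd.DataFrame(rows)


def simulate_growth_cohort(
    arms: dict | None = None,
    n_per_arm: int = 10,
    baseline_mm3: float = 90.0,
    noise_sd: float = 0.1,
    days=None,
    seed: int = 0,
) -> tuple[list[GrowthSeries], SyntheticTruth]:
    """Exponential tumor growth per arm with lognormal measurement noise.

    V(t) = baseline * exp(rate * (t - t0)) * exp(N(0, noise_sd)) at each
    scheduled day; the default schedule measures three times weekly for
    five weeks. Default arms halve the control growth rate under each
    single treatment and quarter it under the combination.
    """
    if arms is None:
        control_rate = np.log(3.0) / 11.0  # tripling in ~11 days untreated
        arms = {"control": control_rate, "drug": control_rate / 1.4,
                "rt": control_rate / 2.0, "drug_rt": control_rate / 3.0}
    if n_per_arm < 1:
        raise ConfigurationError("n_per_arm must be >= 1")
    if days is None:
        days = [1, 3, 5, 8, 10, 12, 15, 17, 19, 22, 24, 26, 29, 31, 33]
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ConfigurationError("measurement schedule must be increasing")
    rng = np.random.default_rng(seed)
    cohort = []
    for arm, rate in arms.items():
        for k in range(n_per_arm):
            noise = rng.normal(0.0, noise_sd, size=days.size) if noise_sd > 0 \
                else np.zeros(days.size)
            values = baseline_mm3 * np.exp(rate * (days - days[0])) * np.exp(noise)
            cohort.append(GrowthSeries(animal=f"{arm}_{k + 1:02d}", arm=arm,
                                       days=days.copy(), values=values))
    truth = SyntheticTruth(seed=seed, growth={
        "arms": {a: float(r) for a, r in arms.items()},
        "n_per_arm": n_per_arm, "baseline_mm3": baseline_mm3,
        "noise_sd": noise_sd, "days": list(map(float, days)),
    })
    return cohort, truth


def simulate_survival_cohort(
    n_per_group: int = 104,
    baseline_hazard: float = np.log(2.0) / 42.0,
    hr: float = 0.6,
    censor_day: float | None = 1500.0,
    seed: int = 0,
    with_expression: bool = False,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Two-group exponential survival with a group hazard ratio.

    Group "g1" has hazard baseline_hazard * hr; "g0" the baseline.
    Administrative censoring at ``censor_day`` (None disables). With
    ``with_expression``, an expression column is added such that the
    hazard-ratio group is the high-expression stratum, so a median split
    recovers the generated groups.
    """
    if baseline_hazard <= 0 or hr <= 0:
        raise ConfigurationError("hazard and hazard ratio must be positive")
    if censor_day is not None and censor_day <= 0:
        raise ConfigurationError("censor_day must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, hazard in (("g0", baseline_hazard), ("g1", baseline_hazard * hr)):
        times = rng.exponential(1.0 / hazard, size=n_per_group)
        for k, t in enumerate(times):
            event = 1
            if censor_day is not None and t > censor_day:
                t, event = censor_day, 0
            rows.append({"subject": f"{group}_{k + 1:03d}", "group": group,
                         "time_days": float(t), "event": event})
    table = pd.DataFrame(rows)
    if with_expression:
        # High expression marks the hr group; jitter keeps values distinct.
        is_g1 = (table["group"] == "g1").to_numpy()
        table["expression"] = np.where(is_g1, 10.0, 5.0) + rng.uniform(
            0.0, 1.0, size=len(table))
    truth = SyntheticTruth(seed=seed, survival={
        "n_per_group": n_per_group, "baseline_hazard": float(baseline_hazard),
        "hr": float(hr),
        "censor_day": None if censor_day is None else float(censor_day),
    })
    return table, truth
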