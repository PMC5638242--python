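"""Hit calling for the chemical (kinase-inhibitor) and genetic (siRNA) screens.

The chemical screen compares cell viability (luminescence units, LU) across
an inhibitor dilution series in two arms: vehicle and a sublethal dose of the
chemotherapy drug. Each arm is modelled with a four-parameter type-1 Weibull
dose-response curve

    viability(x) = c + (d - c) * exp(-exp(b * (ln x - ln e)))

with slope ``b``, lower/upper asymptotes ``c``/``d`` and inflection
concentration ``e``. An inhibitor is a synergizer ("hit") when, at some tested
concentration that survives the exclusion rules, the drug arm sits more than
30% below the vehicle arm.

Kinase hits are the in-vitro targets of hit inhibitors whose activity changes
by more than 50% (in either direction) and that are expressed in the cell
line; genetic hits come from the siRNA screen's Sensitivity Index (SI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InsufficientDataError

TOXICITY_FLOOR_LU = 50_000.0
REDUCTION_THRESHOLD = 0.30
ACTIVITY_CHANGE_THRESHOLD = 50.0
GENETIC_FDR_MAX = 0.05
GENETIC_SI_DEVIATION_MIN = 0.3
GENETIC_SURVIVAL_MIN = 0.5
VALIDATED_CAPACITY = 3.0


def weibull4(x, b, c, d, e):
    """Four-parameter type-1 Weibull dose-response curve."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) * np.exp(-np.exp(b * (np.log(x) - np.log(e))))


@dataclass
class DoseResponseFit:
    b: float
    c: float
    d: float
    e: float
    converged: bool
    residual_sse: float

    def predict(self, x) -> np.ndarray:
        return weibull4(x, self.b, self.c, self.d, self.e)


@dataclass
class InhibitorCall:
    inhibitor: str
    excluded_reason: str  # none | unfit | toxic | overlap
    max_reduction: float
    is_hit: bool


@dataclass
class InputNode:
    """A network input: a hit (kinase/genetic commodity) or a DE gene (sink)."""

    name: str
    commodity: str  # kinase | genetic | expression
    capacity: float
    direction: str | None = None  # up/down for expression nodes


def fit_dose_response(points: list[tuple[float, float]] | np.ndarray) -> DoseResponseFit:
    """Least-squares fit of the four-parameter Weibull curve.

    Internally parameterised as (b, c, delta, e) with d = c + delta so the
    fitted upper asymptote never drops below the lower one. Optimizer failure
    or non-finite parameters yield ``converged=False`` rather than an error.
    """
    pts = np.asarray(points, dtype=float)
    conc, lu = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 4:
        raise InsufficientDataError("dose-response fit needs >= 4 distinct concentrations")

    def model(x, b, c, delta, e):
        return weibull4(x, b, c, c + delta, e)

    lo, hi = float(lu.min()), float(lu.max())
    p0 = [1.0, lo, max(hi - lo, 1e-6), float(np.exp(np.mean(np.log(conc))))]
    bounds = ([-50.0, 0.0, 0.0, 1e-12], [50.0, np.inf, np.inf, np.inf])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, conc, lu, p0=p0, bounds=bounds, maxfev=2000)
    except (RuntimeError, ValueError):
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, False, np.inf)
    if not np.all(np.isfinite(popt)):
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, False, np.inf)
    b, c, delta, e = popt
    sse = float(np.sum((model(conc, *popt) - lu) ** 2))
    return DoseResponseFit(float(b), float(c), float(c + delta), float(e), True, sse)


def _arm_points(df: pd.DataFrame, arm: str) -> pd.DataFrame:
    return df[df["arm"] == arm]


def call_inhibitor_hits(
    measurements: pd.DataFrame,
    toxicity_floor_lu: float = TOXICITY_FLOOR_LU,
    reduction_threshold: float = REDUCTION_THRESHOLD,
    use_fitted: bool = True,
) -> list[InhibitorCall]:
    """Call synergizing inhibitors from the two-arm viability screen.

    Exclusion rules, in order: ``unfit`` when either arm's Weibull fit fails;
    ``toxic`` when the fitted vehicle arm dips below the LU floor at any tested
    concentration; concentrations where the two arms' replicate ranges
    intersect are dropped, and ``overlap`` marks inhibitors with no
    concentration left. Survivors are hits when the viability reduction
    (vehicle - drug)/vehicle exceeds the threshold somewhere; with
    ``use_fitted`` the reduction is read off the fitted curves at the tested
    concentrations, otherwise off raw replicate means.
    """
    calls = []
    for inhibitor, df in measurements.groupby("inhibitor", sort=True):
        veh = _arm_points(df, "vehicle")
        gem = _arm_points(df, "gemcitabine")
        concs = np.sort(df["concentration"].unique())

        fits = {}
        for arm, sub in (("vehicle", veh), ("gemcitabine", gem)):
            try:
                fits[arm] = fit_dose_response(sub[["concentration", "lu"]].to_numpy())
            except InsufficientDataError:
                fits[arm] = DoseResponseFit(np.nan, np.nan, np.nan, np.nan, False, np.inf)
        if not all(f.converged for f in fits.values()):
            calls.append(InhibitorCall(str(inhibitor), "unfit", 0.0, False))
            continue

        veh_curve = fits["vehicle"].predict(concs)
        gem_curve = fits["gemcitabine"].predict(concs)
        veh_means = veh.groupby("concentration")["lu"].mean().reindex(concs).to_numpy()
        gem_means = gem.groupby("concentration")["lu"].mean().reindex(concs).to_numpy()
        veh_toxic = veh_curve if use_fitted else veh_means
        if np.nanmin(veh_toxic) < toxicity_floor_lu:
            calls.append(InhibitorCall(str(inhibitor), "toxic", 0.0, False))
            continue

        # drop concentrations where the arms' replicate min-max ranges intersect
        retained = []
        for i, conc in enumerate(concs):
            v = veh.loc[veh["concentration"] == conc, "lu"]
            g = gem.loc[gem["concentration"] == conc, "lu"]
            if v.empty or g.empty:
                continue
            if v.min() <= g.max() and g.min() <= v.max():
                continue
            retained.append(i)
        if not retained:
            calls.append(InhibitorCall(str(inhibitor), "overlap", 0.0, False))
            continue

        v_vals = (veh_curve if use_fitted else veh_means)[retained]
        g_vals = (gem_curve if use_fitted else gem_means)[retained]
        with np.errstate(divide="ignore", invalid="ignore"):
            reductions = (v_vals - g_vals) / v_vals
        max_red = float(np.clip(np.nanmax(reductions), 0.0, 1.0))
        calls.append(
            InhibitorCall(str(inhibitor), "none", max_red, max_red > reduction_threshold)
        )
    return calls


def map_kinase_hits(
    hit_inhibitors: list[str],
    profiles: pd.DataFrame,
    expressed_genes: set[str],
    change_threshold: float = ACTIVITY_CHANGE_THRESHOLD,
) -> list[InputNode]:
    """Map hit inhibitors to kinase input nodes via the activity matrix.

    ``profiles`` is wide (inhibitor rows x kinase columns, percent of untreated
    activity; NaN = not profiled). A kinase qualifies when some hit inhibitor
    changes its activity by strictly more than the threshold (activation above
    100% counts too) and the kinase is expressed. Capacity is the largest
    absolute activity change over hit inhibitors, on the percent scale.
    """
    expressed = {g.upper() for g in expressed_genes}
    present = [i for i in hit_inhibitors if i in profiles.index]
    for missing in set(hit_inhibitors) - set(present):
        warnings.warn(f"hit inhibitor {missing!r} has no activity profile; no targets added")
    if not present:
        return []
    change = (profiles.loc[present] - 100.0).abs()
    nodes = []
    for kinase in profiles.columns:
        if kinase.upper() not in expressed:
            continue
        col = change[kinase].dropna()
        if col.empty or not (col > change_threshold).any():
            continue
        nodes.append(InputNode(kinase.upper(), "kinase", float(col.max())))
    return sorted(nodes, key=lambda n: n.name)


def select_genetic_hits(
    records: pd.DataFrame,
    fdr_max: float = GENETIC_FDR_MAX,
    si_deviation_min: float = GENETIC_SI_DEVIATION_MIN,
    survival_min: float = GENETIC_SURVIVAL_MIN,
    validated_capacity: float = VALIDATED_CAPACITY,
    capacity_mode: str = "si",
) -> list[InputNode]:
    """Select genetic hits from the siRNA screen table.

    A gene qualifies when FDR < ``fdr_max``, |SI - 1| > ``si_deviation_min``
    (strict), and knockdown survival under vehicle is at least
    ``survival_min``. Capacity is the SI itself (``capacity_mode='si'``) or
    |SI - 1| (``'deviation'``); secondarily validated hits get the uniform
    ``validated_capacity`` either way.
    """
    # strict SI-deviation inequality; epsilon guards the exact-boundary case
    # against binary float error (|1.3 - 1| evaluates a hair above 0.3)
    deviation = (records["si"] - 1.0).abs()
    mask = (
        (records["fdr"] < fdr_max)
        & (deviation > si_deviation_min + 1e-9)
        & (records["vehicle_survival"] >= survival_min)
    )
    nodes = []
    for _, row in records[mask].iterrows():
        if row["validated"]:
            cap = validated_capacity
        elif capacity_mode == "deviation":
            cap = abs(float(row["si"]) - 1.0)
        else:
            cap = float(row["si"])
        nodes.append(InputNode(str(row["gene"]).upper(), "genetic", cap))
    return sorted(nodes, key=lambda n: n.name)
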