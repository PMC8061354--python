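"""Cascade-impactor data reduction: cumulative undersize, MMAD, GSD, FPF.

A cascade impactor (here parameterised for a Next Generation Impactor, NGI)
fractionates an aerosol by aerodynamic diameter: stage *i* collects mass
between its own cutoff diameter ``d_i`` and the next-larger cutoff
``d_{i-1}``; the top stage collects everything above the first cutoff and a
final collector catches everything below the last. The standard reduction
plots the probit (inverse standard-normal) of the cumulative mass fraction
below each cutoff against ``ln d``; for a log-normal aerodynamic
distribution this plot is exactly a straight line with intercept ``ln MMAD``
at probit 0 and slope ``ln GSD``, so two-point bracketing interpolation
recovers both parameters exactly on noiseless log-normal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

#: NGI stage-1..7 aerodynamic cutoff diameters (µm) at 65 L/min.
NGI_CUTOFFS_65LPM = (7.73, 4.20, 2.68, 1.63, 0.90, 0.52, 0.32)

#: Cumulative fraction at +1 probit (84.13th percentile), used for GSD.
_Q84 = float(norm.cdf(1.0))


@dataclass
class ImpactorRun:
    """One impactor experiment: descending stage cutoffs and stage masses.

    ``stage_masses[i]`` is the mass on the stage with cutoff ``cutoffs[i]``
    (i.e. aerodynamic diameters in ``(cutoffs[i], cutoffs[i-1])``);
    ``collector_mass`` is everything below the last cutoff and
    ``pre_stage_mass`` (throat/pre-separator) counts as above the first
    cutoff. Masses are in arbitrary but common units.
    """

    cutoffs: np.ndarray
    stage_masses: np.ndarray
    collector_mass: float = 0.0
    pre_stage_mass: float = 0.0
    flow_rate_lpm: float | None = None

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.stage_masses = np.asarray(self.stage_masses, dtype=float)
        if self.cutoffs.ndim != 1 or len(self.cutoffs) < 2:
            raise ValueError("need at least two stage cutoffs")
        if np.any(self.cutoffs <= 0) or np.any(np.diff(self.cutoffs) >= 0):
            raise ValueError("cutoffs must be positive and strictly decreasing")
        if len(self.stage_masses) != len(self.cutoffs):
            raise ValueError("stage_masses must align with cutoffs")
        if np.any(self.stage_masses < 0) or self.collector_mass < 0 or self.pre_stage_mass < 0:
            raise ValueError("masses must be non-negative")

    @property
    def total_mass(self) -> float:
        """Total recovered mass: pre-stage + stages + collector."""
        return float(self.pre_stage_mass + self.stage_masses.sum() + self.collector_mass)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": "pre", "cutoff_um": np.inf, "mass": self.pre_stage_mass}]
        for i, (c, m) in enumerate(zip(self.cutoffs, self.stage_masses), start=1):
            rows.append({"stage": str(i), "cutoff_um": c, "mass": m})
        rows.append({"stage": "collector", "cutoff_um": 0.0, "mass": self.collector_mass})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, flow_rate_lpm: float | None = None) -> "ImpactorRun":
        df = pd.read_csv(path, dtype={"stage": str})
        pre = float(df.loc[df["stage"] == "pre", "mass"].sum())
        col = float(df.loc[df["stage"] == "collector", "mass"].sum())
        stages = df[~df["stage"].isin(["pre", "collector"])]
        stages = stages.sort_values("cutoff_um", ascending=False)
        return ImpactorRun(
            cutoffs=stages["cutoff_um"].to_numpy(),
            stage_masses=stages["mass"].to_numpy(),
            collector_mass=col,
            pre_stage_mass=pre,
            flow_rate_lpm=flow_rate_lpm,
        )


@dataclass
class AerosolMetrics:
    mmad_um: float
    gsd: float
    fpf_pct: float
    parameters: dict = field(default_factory=dict)


def cumulative_undersize(run: ImpactorRun) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative mass fraction below each stage cutoff.

    Returns ``(ln_cutoffs, fractions)`` where ``fractions[i]`` is the mass
    on all stages with cutoffs smaller than ``cutoffs[i]`` plus the
    collector, divided by the total recovered mass.
    """
    total = run.total_mass
    if total <= 0:
        raise ValueError("total recovered mass is zero; undersize undefined")
    # mass below cutoff i = stages i+1.. + collector
    below = np.concatenate([np.cumsum(run.stage_masses[::-1])[::-1][1:], [0.0]])
    below = below + run.collector_mass
    return np.log(run.cutoffs), below / total


def _interp_ln_d_at(q: float, fractions: np.ndarray, ln_d: np.ndarray) -> float:
    """ln(diameter) at cumulative fraction q by probit-vs-ln(d) bracketing.

    ``fractions`` is increasing with index (cutoffs descend); only stages
    with fractions strictly inside (0, 1) carry probit information.
    """
    ok = (fractions > 0.0) & (fractions < 1.0)
    f, y = fractions[ok], ln_d[ok]
    if len(f) == 0 or not (f[0] <= q <= f[-1]):
        # exact hit on a retained stage still works below; otherwise refuse
        hit = np.flatnonzero(np.isclose(fractions, q))
        if hit.size:
            return float(ln_d[hit[0]])
        raise ValueError(
            f"cumulative fraction {q:.4f} not bracketed by the stage cutoffs; "
            "extrapolation outside the impactor size range is refused"
        )
    j = int(np.searchsorted(f, q))
    if np.isclose(f[j], q):
        return float(y[j])
    p0, p1 = norm.ppf(f[j - 1]), norm.ppf(f[j])
    t = (norm.ppf(q) - p0) / (p1 - p0)
    return float(y[j - 1] + t * (y[j] - y[j - 1]))


def _regress_ln_d_at(q: float, fractions: np.ndarray, ln_d: np.ndarray) -> float:
    ok = (fractions > 0.0) & (fractions < 1.0)
    if ok.sum() < 2:
        raise ValueError("need at least two stages with 0 < fraction < 1 for regression")
    probit = norm.ppf(fractions[ok])
    slope, intercept = np.polyfit(probit, ln_d[ok], 1)
    return float(intercept + slope * norm.ppf(q))


def compute_mmad_gsd(run: ImpactorRun, method: str = "bracket") -> tuple[float, float]:
    """Mass median aerodynamic diameter and geometric standard deviation.

    ``method="bracket"`` (default, USP-style) interpolates probit vs ln(d)
    between the two stages bracketing each quantile; ``method="regression"``
    fits one line through all informative stages. On exact log-normal stage
    masses both coincide.

    MMAD = d50; GSD = d84.13 / d50 (one probit unit up the line).
    """
    ln_d, frac = cumulative_undersize(run)
    # ascending fractions <-> ascending ln d requires reversing stage order
    frac_a, ln_a = frac[::-1], ln_d[::-1]
    est = _interp_ln_d_at if method == "bracket" else _regress_ln_d_at
    if method not in ("bracket", "regression"):
        raise ValueError(f"unknown method {method!r}")
    ln_d50 = est(0.5, frac_a, ln_a)
    try:
        gsd = float(np.exp(est(_Q84, frac_a, ln_a) - ln_d50))
    except ValueError:
        try:  # d84 outside the ladder: use the 16th percentile instead
            gsd = float(np.exp(ln_d50 - est(1.0 - _Q84, frac_a, ln_a)))
        except ValueError:
            # spread not resolved by the stages (e.g. a two-stage split):
            # the median is still well defined, the GSD is not
            gsd = float("nan")
    return float(np.exp(ln_d50)), gsd


def compute_fpf(
    run: ImpactorRun,
    stage_lo: int = 2,
    stage_hi: int = 6,
    denominator: str = "recovered",
) -> float:
    """Fine particle fraction: percent of mass in the stage-window size band.

    The window is delimited by the cutoff diameters of the 1-indexed
    stages ``stage_lo`` and ``stage_hi``: FPF is the mass with
    aerodynamic diameter between cutoff(stage_hi) and cutoff(stage_lo) —
    for the NGI at 65 L/min and the default window 2–6, the respirable
    band 0.52–4.20 µm. On analytic log-normal stage masses this equals
    ``CDF(cutoff_lo) − CDF(cutoff_hi)``.

    ``denominator`` is the total recovered mass (default) or ``"stages"``
    (impaction stages only, pre-stage and collector excluded).
    """
    if not (1 <= stage_lo <= stage_hi <= len(run.cutoffs)):
        raise ValueError(f"stage window {stage_lo}..{stage_hi} out of range")
    if denominator == "recovered":
        total = run.total_mass
    elif denominator == "stages":
        total = float(run.stage_masses.sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total <= 0:
        raise ValueError("total mass is zero; FPF undefined")
    # stage i collects diameters in (cutoff_i, cutoff_{i-1}]; the band
    # (cutoff_hi, cutoff_lo] is therefore stages lo+1 .. hi
    window = float(run.stage_masses[stage_lo:stage_hi].sum())
    return 100.0 * window / total


def compute_metrics(
    run: ImpactorRun,
    stage_lo: int = 2,
    stage_hi: int = 6,
    method: str = "bracket",
) -> AerosolMetrics:
    """Convenience wrapper computing MMAD, GSD and FPF in one call."""
    mmad, gsd = compute_mmad_gsd(run, method=method)
    fpf = compute_fpf(run, stage_lo, stage_hi)
    return AerosolMetrics(
        mmad_um=mmad,
        gsd=gsd,
        fpf_pct=fpf,
        parameters={"stage_lo": stage_lo, "stage_hi": stage_hi, "method": method},
    )
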