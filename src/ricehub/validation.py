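"""Statistical validation of the simulated production series.

The simulator is validated against an externally expected pandemic effect:
a 3.28% reduction of agricultural production.  For each simulation
repetition i the observed relative production change is

    O_i = (mean normal-phase production - mean pandemic production)
          / mean normal-phase production

(positive = decrease), and the chi-square goodness-of-fit statistic

    chi2 = sum_i (O_i - E_i)^2 / E_i

is compared against the upper-alpha quantile at k - 1 degrees of freedom,
with E_i the constant expected reduction.  The null hypothesis (simulated
changes consistent with the expected reduction) is retained iff chi2 is
strictly below the critical value.

The module also classifies pandemic case curves into single- vs multi-wave
profiles and runs the sensitivity analysis of the recovered-to-susceptible
probability, whose expected signature is a multi-wave frequency that falls
as the probability falls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import PHASE_COVID, PHASE_NORMAL

__all__ = [
    "GoFResult",
    "WaveProfile",
    "EXPECTED_REDUCTION",
    "production_change",
    "chi_square",
    "gof_test",
    "count_waves",
    "resusceptibility_sensitivity",
]

#: expected relative reduction of agricultural production under the pandemic
EXPECTED_REDUCTION = 0.0328


@dataclass(frozen=True)
class GoFResult:
    chi2: float
    k: int  # number of simulations
    df: int  # k - 1
    alpha: float
    critical_value: float
    reject_h0: bool

    def __str__(self):  # small report used by the CLI
        verdict = "rejected" if self.reject_h0 else "not rejected"
        return (
            f"chi2 = {self.chi2:.3f} on df = {self.df} "
            f"(critical value {self.critical_value:.3f} at alpha = {self.alpha}); "
            f"H0 {verdict}"
        )


@dataclass(frozen=True)
class WaveProfile:
    new_cases: np.ndarray  # daily new detected cases
    n_waves: int
    window: int
    threshold: float  # absolute threshold on the smoothed series


def production_change(series: pd.DataFrame) -> pd.Series:
    """Per-repetition relative production difference between phases.

    Production is pooled over all regions; O_i > 0 means the pandemic-phase
    mean fell below the normal-phase mean.
    """
    needed = {PHASE_NORMAL, PHASE_COVID}
    present = set(series["phase"].unique())
    if not needed <= present:
        raise ValueError(f"series must contain phases {sorted(needed)}")
    means = series.groupby(["repetition", "phase"])["production_tons"].mean().unstack("phase")
    if (means[PHASE_NORMAL] == 0).any():
        raise ValueError("zero normal-phase production: relative change undefined")
    obs = (means[PHASE_NORMAL] - means[PHASE_COVID]) / means[PHASE_NORMAL]
    obs.name = "production_change"
    return obs


def chi_square(observed, expected) -> float:
    """Goodness-of-fit statistic sum (O_i - E_i)^2 / E_i."""
    o = np.asarray(observed, dtype=float).ravel()
    e = np.asarray(expected, dtype=float).ravel()
    if o.shape != e.shape:
        raise ValueError("observed and expected lengths differ")
    if np.any(e == 0):
        raise ValueError("expected values must be nonzero")
    return float(np.sum((o - e) ** 2 / e))


def gof_test(observed, expected_value: float = EXPECTED_REDUCTION, alpha: float = 0.05) -> GoFResult:
    """Chi-square test of the observed changes against a constant expectation.

    H0 (no significant difference) is retained iff chi2 < critical value,
    the upper-alpha chi-square quantile at k - 1 degrees of freedom.
    """
    o = np.asarray(observed, dtype=float).ravel()
    k = o.size
    if k < 2:
        raise ValueError("need at least 2 observations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    chi2 = chi_square(o, np.full(k, expected_value))
    critical = float(stats.chi2.ppf(1.0 - alpha, df=k - 1))
    return GoFResult(
        chi2=chi2,
        k=k,
        df=k - 1,
        alpha=alpha,
        critical_value=critical,
        reject_h0=chi2 > critical,
    )


def count_waves(new_cases, window: int = 14, threshold_frac: float = 0.10) -> WaveProfile:
    """Count epidemic waves in a daily new-case series.

    The series is smoothed with a centered moving average of ``window``
    days; a wave is a maximal run above ``threshold_frac`` of the global
    smoothed peak, where runs separated by sub-threshold gaps shorter than
    ``window`` days merge into one wave.
    """
    cases = np.asarray(new_cases, dtype=float).ravel()
    if cases.size == 0:
        raise ValueError("empty case series")
    if np.any(cases < 0):
        raise ValueError("case counts must be nonnegative")
    smoothed = (
        pd.Series(cases).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    peak = smoothed.max()
    threshold = threshold_frac * peak
    if peak <= 0:
        return WaveProfile(new_cases=cases, n_waves=0, window=window, threshold=threshold)

    above = smoothed > threshold
    waves = 0
    in_wave = False
    run_below = window  # pretend a long quiet spell before day 0
    for flag in above:
        if flag:
            if not in_wave and run_below >= window:
                waves += 1
            in_wave = True
            run_below = 0
        else:
            run_below += 1
            if run_below >= window:
                in_wave = False
    return WaveProfile(new_cases=cases, n_waves=waves, window=window, threshold=threshold)


def resusceptibility_sensitivity(
    probs,
    reps: int,
    config=None,
    seed: int = 0,
    window: int = 14,
    threshold_frac: float = 0.10,
) -> pd.DataFrame:
    """Multi- vs single-wave counts per recovered-to-susceptible probability.

    Runs ``reps`` independent simulations per probability and classifies
    each run's city-summed daily new detected cases as multi-wave
    (>= 2 waves) or single-wave.  Rows sum to ``reps``.
    """
    from .abm import default_config, run_simulation

    probs = list(probs)
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError("probabilities must lie in [0, 1]")
    if config is None:
        config = default_config()

    rows = []
    for pi, prob in enumerate(probs):
        cfg = replace(config, epi=replace(config.epi, resusceptible_prob=prob))
        result = run_simulation(cfg, n_repetitions=reps, seed=seed + pi)
        covid = result.epidemic[result.epidemic["phase"] == PHASE_COVID]
        daily = covid.groupby(["repetition", "day"])["new_cases"].sum()
        multi = 0
        for rep in range(reps):
            profile = count_waves(
                daily.loc[rep].to_numpy(), window=window, threshold_frac=threshold_frac
            )
            multi += profile.n_waves >= 2
        rows.append(
            {
                "resusceptible_prob": prob,
                "n_simulations": reps,
                "multiple_waves": multi,
                "single_wave": reps - multi,
            }
        )
    return pd.DataFrame(rows)
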