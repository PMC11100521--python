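"""Change statistics: normalized metric changes, MEC reference, gradient
similarity mapping, paired significance tests, and firing-rate/ISI analysis.

All change quantities are computed as dimensionless fractions; multiply by
100 when rendering the conventional percentage form.

* experimental change: |μ(laser) − μ(control)| / |μ(control)| per metric;
* model change: |min − max| / |max| over a parameter-sweep's metric values;
* MEC (mean experimental change): across-experiment mean ± SD of the
  experimental change, defining the similarity range (μMEC ± 2σMEC);
* gradient value: affine mapping of a model change onto [Vmin, Vmax] with
  Vmin = max(0, μMEC − 2σMEC), Vmax = μMEC + 2σMEC;
* significance: two-sided paired t-tests on per-experiment means
  (control vs laser, control vs recovery) with a Bonferroni-corrected
  high-significance threshold of 0.01/4 for the four metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METRIC_COLUMNS", "HIGH_SIGNIFICANCE_ALPHA",
    "TrialTriplet", "MECReference", "GradientScore", "FiringRateSummary",
    "experimental_change", "model_change", "mec", "gradient_value",
    "paired_significance", "paired_significance_from_means", "firing_rate_analysis", "normalize_to_first_control",
]

METRIC_COLUMNS = ("duration_ms", "amplitude_mV", "depol_slope", "repol_slope")
#: Bonferroni-corrected threshold for "high significance" over four metrics.
HIGH_SIGNIFICANCE_ALPHA = 0.01 / 4

#: metrics whose change statistics compare magnitudes (slopes are signed).
_MAGNITUDE = True


@dataclass
class TrialTriplet:
    """Per-spike metric tables and spike times for one control/laser/recovery
    experiment."""

    control: pd.DataFrame
    laser: pd.DataFrame
    recovery: pd.DataFrame
    duration_s: Mapping[str, float] = field(default_factory=dict)
    spike_times: Mapping[str, np.ndarray] = field(default_factory=dict)

    TRIALS = ("control", "laser", "recovery")

    def table(self, trial: str) -> pd.DataFrame:
        if trial not in self.TRIALS:
            raise KeyError(f"trial must be one of {self.TRIALS}")
        return getattr(self, trial)

    def metric_means(self, trial: str) -> pd.Series:
        tab = self.table(trial)
        if tab.empty:
            raise ValueError(f"{trial} trial has no spikes")
        return tab[list(METRIC_COLUMNS)].abs().mean()


@dataclass
class MECReference:
    """Across-experiment mean ± SD of the experimental change, per metric."""

    mu: Mapping[str, float]
    sigma: Mapping[str, float]
    n_experiments: int


@dataclass
class GradientScore:
    value: float        # the change being scored (fraction)
    score: float        # affine position in [Vmin, Vmax]
    in_range: bool
    vmin: float
    vmax: float


def _mean_abs(values: Iterable[float]) -> float:
    arr = np.abs(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise ValueError("empty metric collection")
    return float(arr.mean())


def experimental_change(control_values: Iterable[float],
                        laser_values: Iterable[float]) -> float:
    """|μ(laser) − μ(control)| / |μ(control)| for one metric of one experiment.

    Slopes enter as magnitudes so that the change of a negative-valued
    metric is comparable with the positive ones.
    """
    mc = _mean_abs(control_values)
    ml = _mean_abs(laser_values)
    if mc == 0:
        raise ZeroDivisionError("control mean is zero; change undefined")
    return abs(ml - mc) / abs(mc)


def model_change(sweep_values: Iterable[float]) -> float:
    """|min − max| / |max| over the metric values of a parameter sweep."""
    arr = np.abs(np.asarray(list(sweep_values), dtype=float))
    if arr.size == 0:
        raise ValueError("empty sweep")
    vmax = arr.max()
    if vmax == 0:
        return 0.0
    return float(abs(arr.min() - vmax) / vmax)


def mec(per_experiment_changes: Mapping[str, Sequence[float]] | Sequence[float],
        ) -> MECReference:
    """MEC reference from per-experiment experimental changes.

    Accepts either a mapping metric → sequence of per-experiment changes or
    a bare sequence (treated as a single unnamed metric ``"metric"``).
    """
    if not isinstance(per_experiment_changes, Mapping):
        per_experiment_changes = {"metric": per_experiment_changes}
    mu, sigma, n = {}, {}, None
    for name, vals in per_experiment_changes.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise ValueError(f"no experiments for metric {name!r}")
        mu[name] = float(arr.mean())
        sigma[name] = float(arr.std(ddof=0))
        n = arr.size if n is None else n
    return MECReference(mu=mu, sigma=sigma, n_experiments=int(n))


def gradient_value(value: float, mu_mec: float, sigma_mec: float) -> GradientScore:
    """Map a change onto the experimental similarity range (μMEC ± 2σMEC).

    Vmin is floored at 0 because all changes are absolute values. The score
    is 0 at Vmin, 1 at Vmax and 0.5 at the midpoint; ``in_range`` flags
    whether the value lies inside [Vmin, Vmax].
    """
    vmin = max(0.0, mu_mec - 2.0 * sigma_mec)
    vmax = mu_mec + 2.0 * sigma_mec
    if not vmax > vmin:
        raise ValueError("degenerate similarity range (Vmax must exceed Vmin)")
    score = (value - vmin) / (vmax - vmin)
    return GradientScore(value=value, score=float(score),
                         in_range=bool(vmin <= value <= vmax),
                         vmin=vmin, vmax=vmax)


def paired_significance_from_means(
    means: Mapping[str, Mapping[str, np.ndarray]],
    metrics: Sequence[str] = METRIC_COLUMNS,
    alpha: float = HIGH_SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Paired t-tests given per-experiment metric means.

    ``means[trial][metric]`` is the vector of per-experiment means (aligned
    across trials). This is the decision core of ``paired_significance``;
    identical pairs yield p = 1 (a zero-variance difference is never
    flagged).
    """
    rows = []
    for metric in metrics:
        ctrl = np.asarray(means["control"][metric], dtype=float)
        if ctrl.size < 2:
            raise ValueError("need at least two experiments for a paired test")
        for other in ("laser", "recovery"):
            if other not in means:
                continue
            vals = np.asarray(means[other][metric], dtype=float)
            diff = ctrl - vals
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.ttest_rel(ctrl, vals).pvalue)
                if np.isnan(p):  # zero-variance differences: not significant
                    p = 1.0
            rows.append({"metric": metric, "comparison": f"control_vs_{other}",
                         "p_value": p, "high_significance": p < alpha})
    return pd.DataFrame(rows)


def paired_significance(
    triplets: Sequence[TrialTriplet],
    metrics: Sequence[str] = METRIC_COLUMNS,
    alpha: float = HIGH_SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Two-sided paired t-tests on per-experiment metric means.

    The pairing unit is the experiment (per-experiment means), not the
    individual spike, to avoid pseudo-replication. Returns one row per
    metric × comparison (control-vs-laser, control-vs-recovery) with the
    p-value and the Bonferroni-gated high-significance flag p < 0.01/4.
    """
    if len(triplets) < 2:
        raise ValueError("need at least two experiments for a paired test")
    means = {
        trial: {m: np.array([t.metric_means(trial)[m] for t in triplets])
                for m in metrics}
        for trial in TrialTriplet.TRIALS
    }
    return paired_significance_from_means(means, metrics=metrics, alpha=alpha)


@dataclass
class FiringRateSummary:
    """AFR per trial, ISI histograms and excitation/inhibition classification."""

    afr: Mapping[str, float]              # spikes / s per trial
    isi_histograms: Mapping[str, np.ndarray]
    isi_bin_edges: np.ndarray
    classification: str                   # no-change | excitation | inhibition
    laser_relative_change: float
    recovery_relative_change: float
    included: bool                        # recovery within the 10% gate


def firing_rate_analysis(
    spike_times: Mapping[str, np.ndarray],
    duration_s: Mapping[str, float],
    change_threshold: float = 0.10,
    isi_bin_ms: float = 50.0,
) -> FiringRateSummary:
    """Firing-rate triplet analysis with the 10% classification rule.

    AFR = spike count / trial duration. The triplet is *included* when the
    recovery AFR returns to within ``change_threshold`` (10%) of the control;
    the laser trial is classified as excitation (relative change > +10%),
    inhibition (< −10%) or no-change otherwise. ISI histograms share bin
    edges across the three trials.
    """
    afr = {}
    for trial in TrialTriplet.TRIALS:
        if duration_s[trial] <= 0:
            raise ValueError(f"non-positive duration for {trial}")
        afr[trial] = len(spike_times[trial]) / duration_s[trial]
    if afr["control"] == 0:
        raise ValueError("control trial has no spikes; AFR change undefined")
    laser_rel = (afr["laser"] - afr["control"]) / afr["control"]
    rec_rel = (afr["recovery"] - afr["control"]) / afr["control"]
    included = abs(rec_rel) <= change_threshold
    if laser_rel > change_threshold:
        classification = "excitation"
    elif laser_rel < -change_threshold:
        classification = "inhibition"
    else:
        classification = "no-change"

    isis = {t: np.diff(np.sort(np.asarray(spike_times[t], dtype=float)))
            for t in TrialTriplet.TRIALS}
    all_isis = np.concatenate([v for v in isis.values() if v.size])
    if all_isis.size:
        hi = float(all_isis.max())
        edges = np.arange(0.0, hi + 2 * isi_bin_ms, isi_bin_ms)
    else:
        edges = np.array([0.0, isi_bin_ms])
    hists = {t: np.histogram(isis[t], bins=edges)[0] for t in isis}
    return FiringRateSummary(
        afr=afr, isi_histograms=hists, isi_bin_edges=edges,
        classification=classification,
        laser_relative_change=float(laser_rel),
        recovery_relative_change=float(rec_rel),
        included=bool(included),
    )


def normalize_to_first_control(triplet: TrialTriplet) -> TrialTriplet:
    """Divide every metric by the mean of the first control (per experiment).

    This is the per-experiment normalization applied before pooling
    experiments in summary (violin-style) views.
    """
    ref = triplet.metric_means("control")
    out = {}
    for trial in TrialTriplet.TRIALS:
        tab = triplet.table(trial).copy()
        for col in METRIC_COLUMNS:
            tab[col] = tab[col].abs() / ref[col]
        out[trial] = tab
    return TrialTriplet(out["control"], out["laser"], out["recovery"],
                        duration_s=triplet.duration_s,
                        spike_times=triplet.spike_times)
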