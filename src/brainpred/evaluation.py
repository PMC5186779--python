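"""Scoring of predicted networks against real ones.

Two complementary views of prediction quality are provided:

* **topological** — relative errors of eight graph properties between the
  real and predicted network, collapsed into a single *energy*
  E = 1 / sum(relative errors);
* **edge-wise** — *prediction power*, 10*log10 of the ratio of the model's
  edge-recovery rate to that of a random prediction with the same edge
  count (0 dB = chance level).

Group statistics (paired signed-rank tests with Benjamini-Hochberg FDR,
one-way ANOVA across models, energy-vs-power correlation) operate on
per-subject vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import BrainNetwork, DegreeFit

__all__ = [
    "relative_error",
    "degree_distribution_error",
    "energy",
    "prediction_power",
    "paired_property_test",
    "bh_fdr",
    "model_anova",
    "energy_power_correlation",
    "EvaluationReport",
    "evaluate_models",
]

#: sentinel for a perfect prediction (zero summed error -> infinite energy)
ENERGY_CAP = 1e6
#: floor (dB) for a prediction recovering zero true edges
POWER_FLOOR_DB = -100.0

SCALAR_PROPERTIES = ("R", "C", "L", "E_glob", "E_loc", "Q", "T")


def relative_error(pd_value: float, pm_value: float) -> float:
    """Relative error |(pd - pm)/pd| * 100, in percent.

    ``pd`` is the real-network property value, ``pm`` the predicted one.
    """
    if pd_value == 0:
        raise ValueError("relative error undefined for a zero reference value")
    return abs((pd_value - pm_value) / pd_value) * 100.0


def degree_distribution_error(fit_real: DegreeFit, fit_pred: DegreeFit) -> float:
    """Mean of the relative errors of the fitted exponent and cutoff degree,
    in percent."""
    re_alpha = relative_error(fit_real.alpha, fit_pred.alpha)
    re_kc = relative_error(fit_real.k_c, fit_pred.k_c)
    return (re_alpha + re_kc) / 2.0


def energy(re_values: dict[str, float] | np.ndarray) -> float:
    """Energy E = 1 / sum of the eight relative errors (as fractions).

    Accepts a mapping property -> percent error or an array of the eight
    percent errors.  A zero sum (perfect prediction) returns the capped
    sentinel ``ENERGY_CAP``.
    """
    if isinstance(re_values, dict):
        arr = np.array(list(re_values.values()), dtype=float)
    else:
        arr = np.asarray(re_values, dtype=float)
    if arr.size != 8:
        raise ValueError(f"energy requires all 8 relative errors, got {arr.size}")
    if np.any(np.isnan(arr)):
        return float("nan")
    total = arr.sum() / 100.0  # percent -> fraction
    if total == 0:
        return ENERGY_CAP
    return 1.0 / total


def prediction_power(
    predicted: BrainNetwork,
    real: BrainNetwork,
    baseline: str = "analytic",
    n_random: int = 100,
    seed: int = 0,
) -> float:
    """Prediction power in dB: 10*log10(Pre_M / Pre_R).

    Pre_M is the fraction of real edges recovered by the prediction.  The
    random baseline Pre_R is either the analytic expectation
    m / (n(n-1)/2) of a uniform random prediction with the same edge count,
    or a seeded Monte-Carlo mean over ``n_random`` random edge sets
    (zero-overlap draws excluded from the mean).
    """
    if predicted.labels != real.labels:
        raise ValueError("node sets differ between predicted and real network")
    m = real.n_edges
    if predicted.n_edges != m:
        raise ValueError(
            f"edge counts differ: predicted {predicted.n_edges}, real {m}"
        )
    if m == 0:
        raise ValueError("real network has no edges")
    n = real.n_nodes
    n_pairs = n * (n - 1) // 2
    overlap = int(np.sum(predicted.adjacency * real.adjacency)) // 2
    pre_m = overlap / m
    if baseline == "analytic":
        pre_r = m / n_pairs
    elif baseline == "monte_carlo":
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(n, k=1)
        real_flat = real.adjacency[iu, ju]
        overlaps = []
        for _ in range(n_random):
            pick = rng.choice(n_pairs, size=m, replace=False)
            ov = int(real_flat[pick].sum())
            if ov > 0:
                overlaps.append(ov / m)
        if not overlaps:
            pre_r = 1.0 / (m * n_random)  # vanishing baseline
        else:
            pre_r = float(np.mean(overlaps))
    else:
        raise ValueError("baseline must be 'analytic' or 'monte_carlo'")
    if pre_m == 0:
        return POWER_FLOOR_DB
    return 10.0 * math.log10(pre_m / pre_r)


def paired_property_test(
    real_values: np.ndarray, pred_values: np.ndarray
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-subject values.

    Uses the exact null distribution for n <= 25.  Identical vectors carry
    no evidence of a difference and return p = 1.
    """
    real_values = np.asarray(real_values, dtype=float)
    pred_values = np.asarray(pred_values, dtype=float)
    if real_values.shape != pred_values.shape or real_values.ndim != 1:
        raise ValueError("paired vectors must be 1D and of equal length")
    if real_values.size < 6:
        raise ValueError("at least 6 pairs required")
    diffs = real_values - pred_values
    if np.all(diffs == 0):
        return 1.0
    method = "exact" if real_values.size <= 25 else "approx"
    res = stats.wilcoxon(
        real_values, pred_values, alternative="two-sided", method=method
    )
    return float(res.pvalue)


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def model_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across model groups: (F, p)."""
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if all(np.var(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.var(means) == 0:
            raise ValueError("degenerate ANOVA: all values identical")
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def energy_power_correlation(
    e_values: np.ndarray, pp_values: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of energy vs prediction power
    across subjects."""
    e_values = np.asarray(e_values, dtype=float)
    pp_values = np.asarray(pp_values, dtype=float)
    if e_values.shape != pp_values.shape or e_values.size < 4:
        raise ValueError("equal-length vectors of at least 4 values required")
    if np.var(e_values) == 0 or np.var(pp_values) == 0:
        raise ValueError("degenerate correlation: zero variance")
    r, p = stats.pearsonr(e_values, pp_values)
    return float(r), float(p)


@dataclass
class EvaluationReport:
    """Per-subject and group-level evaluation of all prediction models.

    Attributes
    ----------
    indices : model index names, in evaluation order.
    relative_errors : index -> property -> per-subject percent errors.
    energies : index -> per-subject E values.
    powers : index -> per-subject prediction power (dB).
    property_tests : index -> property -> (p-value, FDR-rejected flag).
    anova_energy, anova_power : (F, p) across models.
    energy_power_corr : index -> (r, p).
    """

    indices: list[str]
    relative_errors: dict = field(default_factory=dict)
    energies: dict = field(default_factory=dict)
    powers: dict = field(default_factory=dict)
    property_tests: dict = field(default_factory=dict)
    anova_energy: tuple[float, float] | None = None
    anova_power: tuple[float, float] | None = None
    energy_power_corr: dict = field(default_factory=dict)
    q: float = 0.05

    def mean_energy(self, index: str) -> float:
        return float(np.nanmean(self.energies[index]))

    def mean_power(self, index: str) -> float:
        return float(np.mean(self.powers[index]))

    def to_dict(self) -> dict:
        return {
            "indices": self.indices,
            "q": self.q,
            "relative_errors": {
                k: {p: list(map(float, v)) for p, v in d.items()}
                for k, d in self.relative_errors.items()
            },
            "energies": {k: list(map(float, v)) for k, v in self.energies.items()},
            "powers": {k: list(map(float, v)) for k, v in self.powers.items()},
            "property_tests": {
                k: {p: [float(pv), bool(rej)] for p, (pv, rej) in d.items()}
                for k, d in self.property_tests.items()
            },
            "anova_energy": list(self.anova_energy) if self.anova_energy else None,
            "anova_power": list(self.anova_power) if self.anova_power else None,
            "energy_power_corr": {
                k: [float(r), float(p)] for k, (r, p) in self.energy_power_corr.items()
            },
        }

    def summary(self) -> str:
        lines = ["Model evaluation summary", "=" * 56]
        lines.append(f"{'index':8s} {'mean E':>10s} {'mean PP (dB)':>14s}")
        for idx in sorted(self.indices, key=self.mean_power, reverse=True):
            lines.append(
                f"{idx:8s} {self.mean_energy(idx):10.4f} {self.mean_power(idx):14.3f}"
            )
        if self.anova_energy:
            lines.append(
                f"ANOVA over models, E:  F = {self.anova_energy[0]:.3f}, "
                f"p = {self.anova_energy[1]:.3g}"
            )
        if self.anova_power:
            lines.append(
                f"ANOVA over models, PP: F = {self.anova_power[0]:.3f}, "
                f"p = {self.anova_power[1]:.3g}"
            )
        return "\n".join(lines)


def evaluate_models(
    real_profiles: dict,
    pred_profiles: dict,
    powers: dict,
    q: float = 0.05,
) -> EvaluationReport:
    """Assemble the full multi-subject, multi-model evaluation report.

    Parameters
    ----------
    real_profiles : subject -> TopologyProfile of the real network.
    pred_profiles : index -> subject -> TopologyProfile of the prediction.
    powers : index -> subject -> prediction power (dB).
    q : FDR level for the paired property tests.

    Energies use the AUC-over-sparsity scalar of each of the 7 scalar
    properties plus the degree-fit error at the reference sparsity.
    """
    indices = sorted(pred_profiles)
    subjects = sorted(real_profiles)
    missing = [
        (idx, s) for idx in indices for s in subjects if s not in pred_profiles[idx]
    ]
    if missing:
        raise ValueError(f"missing prediction profiles for: {missing}")

    report = EvaluationReport(indices=indices, q=q)
    for idx in indices:
        per_prop: dict[str, list[float]] = {p: [] for p in SCALAR_PROPERTIES}
        per_prop["P(k)"] = []
        e_vals, pp_vals = [], []
        for s in subjects:
            rp = real_profiles[s]
            pp = pred_profiles[idx][s]
            re_vec = []
            for prop in SCALAR_PROPERTIES:
                rv, pv = rp.auc[prop], pp.auc[prop]
                err = (
                    relative_error(rv, pv)
                    if (rv is not None and pv is not None and rv != 0)
                    else float("nan")
                )
                per_prop[prop].append(err)
                re_vec.append(err)
            fr, fp = rp.reference_degree_fit(), pp.reference_degree_fit()
            err_pk = (
                degree_distribution_error(fr, fp)
                if (fr is not None and fp is not None)
                else float("nan")
            )
            per_prop["P(k)"].append(err_pk)
            re_vec.append(err_pk)
            e_vals.append(energy(np.array(re_vec)))
            pp_vals.append(powers[idx][s])
        report.relative_errors[idx] = per_prop
        report.energies[idx] = np.array(e_vals)
        report.powers[idx] = np.array(pp_vals)

    # paired tests per property per model on AUC values, FDR across the
    # 7 models for each property (degree distribution excluded)
    pvals_by_prop: dict[str, list[float]] = {}
    for prop in SCALAR_PROPERTIES:
        pvals = []
        for idx in indices:
            rv = np.array([real_profiles[s].auc[prop] for s in subjects], float)
            pv = np.array([pred_profiles[idx][s].auc[prop] for s in subjects], float)
            ok = ~(np.isnan(rv) | np.isnan(pv))
            if ok.sum() >= 6:
                pvals.append(paired_property_test(rv[ok], pv[ok]))
            else:
                pvals.append(float("nan"))
        pvals_by_prop[prop] = pvals
    for prop, pvals in pvals_by_prop.items():
        arr = np.array(pvals)
        ok = ~np.isnan(arr)
        flags = np.zeros(len(indices), dtype=bool)
        if ok.any():
            flags[ok] = bh_fdr(arr[ok], q=q)
        for j, idx in enumerate(indices):
            report.property_tests.setdefault(idx, {})[prop] = (pvals[j], flags[j])

    if len(indices) >= 2 and len(subjects) >= 2:
        e_groups = [report.energies[idx] for idx in indices]
        e_groups = [g[~np.isnan(g)] for g in e_groups]
        if all(g.size >= 2 for g in e_groups):
            try:
                report.anova_energy = model_anova(e_groups)
            except ValueError:
                report.anova_energy = None
        try:
            report.anova_power = model_anova([report.powers[i] for i in indices])
        except ValueError:
            report.anova_power = None

    if len(subjects) >= 4:
        for idx in indices:
            e = report.energies[idx]
            p = report.powers[idx]
            ok = ~np.isnan(e)
            try:
                report.energy_power_corr[idx] = energy_power_correlation(
                    e[ok], p[ok]
                )
            except ValueError:
                pass
    return report
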