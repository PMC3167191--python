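"""Banded single-variable and mixed-variable sequential threshold classifiers.

The single-variable rule on a standardized pulse quantity z uses two criteria
α ≥ β:

    z ≥ α  → excess,    z < β  → deficient,    β ≤ z < α → intermediate.

The mixed-variable model resolves the intermediate band of a primary variable
with a secondary variable carrying its own criteria γ ≥ δ (γ = δ by default,
which makes the decision total).  Boundaries are inclusive for the excess
side ("≥") throughout.

Threshold fitting is an exhaustive grid search over candidate cuts at the
midpoints of sorted unique z values (plus ±∞), maximizing training accuracy
with MCC as first tie-breaker and the narrowest primary band |α−β| as second,
so that when the secondary variable buys nothing the fit degenerates to the
single-threshold rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .metrics import CLASSES, DEFICIENT, EXCESS, ConfusionTable, accuracy, confusion, mcc

INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class ThresholdRule:
    """One banded rule on a standardized variable: excess ≥ alpha, deficient < beta."""

    variable_name: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha >= self.beta):
            raise ValueError(f"alpha must be >= beta, got {self.alpha} < {self.beta}")


@dataclass(frozen=True)
class MixedThresholdModel:
    """Sequential two-stage rule: primary band, secondary resolves the band.

    The decision is total only when the secondary band is degenerate
    (gamma == delta) or a midpoint tie-break is enabled, which splits the
    secondary band at (gamma+delta)/2.
    """

    primary: ThresholdRule
    secondary: ThresholdRule
    tie_break: str | None = None  # None or "midpoint"

    def __post_init__(self) -> None:
        if self.secondary.alpha != self.secondary.beta and self.tie_break != "midpoint":
            raise ValueError(
                "secondary band gamma > delta leaves inputs undecided; "
                "set tie_break='midpoint' or use gamma == delta"
            )
        if self.tie_break not in (None, "midpoint"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")

    @property
    def gamma(self) -> float:
        return self.secondary.alpha

    @property
    def delta(self) -> float:
        return self.secondary.beta

    def to_dict(self) -> dict:
        return {
            "primary": {"var": self.primary.variable_name,
                        "alpha": self.primary.alpha, "beta": self.primary.beta},
            "secondary": {"var": self.secondary.variable_name,
                          "gamma": self.gamma, "delta": self.delta},
            "tie_break": self.tie_break,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixedThresholdModel":
        return cls(
            primary=ThresholdRule(d["primary"]["var"], d["primary"]["alpha"],
                                  d["primary"]["beta"]),
            secondary=ThresholdRule(d["secondary"]["var"], d["secondary"]["gamma"],
                                    d["secondary"]["delta"]),
            tie_break=d.get("tie_break"),
        )


def classify_single(z: float, rule: ThresholdRule) -> str:
    """Apply one banded rule; returns deficient/excess/intermediate."""
    if z >= rule.alpha:
        return EXCESS
    if z < rule.beta:
        return DEFICIENT
    return INTERMEDIATE


def classify_mixed(z_primary: float, z_secondary: float,
                   model: MixedThresholdModel) -> str:
    """Apply the two-stage rule; always returns deficient or excess."""
    first = classify_single(z_primary, model.primary)
    if first != INTERMEDIATE:
        return first
    second = classify_single(z_secondary, model.secondary)
    if second != INTERMEDIATE:
        return second
    # only reachable with tie_break="midpoint" (validated at construction)
    mid = 0.5 * (model.gamma + model.delta)
    return EXCESS if z_secondary >= mid else DEFICIENT


def predict_mixed(z_primary, z_secondary, model: MixedThresholdModel) -> list[str]:
    return [classify_mixed(p, s, model)
            for p, s in zip(np.asarray(z_primary, float), np.asarray(z_secondary, float))]


def _candidate_cuts(z: np.ndarray) -> np.ndarray:
    """Midpoints of sorted unique values, with ±∞ sentinels."""
    u = np.unique(z)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _mcc_from_counts(tp, fn, fp, tn):
    tp, fn, fp, tn = (np.asarray(a, float) for a in (tp, fn, fp, tn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (tp * tn - fp * fn) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


@dataclass(frozen=True)
class ThresholdFit:
    """Result of a grid-search threshold fit."""

    model: MixedThresholdModel
    training_accuracy: float
    training_mcc: float
    n: int


def fit_thresholds(z_primary, z_secondary, labels,
                   primary_name: str = "PP_avg",
                   secondary_name: str = "PP_max") -> ThresholdFit:
    """Exhaustive grid search for the mixed-variable model (γ = δ enforced).

    Candidate α, β cuts come from the primary variable, γ cuts from the
    secondary.  The objective is training accuracy; ties are broken by MCC,
    then by the narrowest primary band |α−β|, then deterministically by scan
    order.  Inputs are expected already standardized.

    The search space nests the single-threshold rule (α = β), so the fitted
    training accuracy is never below the best single-cut accuracy and never
    below the majority-class rate.
    """
    zp = np.asarray(z_primary, dtype=float)
    zs = np.asarray(z_secondary, dtype=float)
    y = _as_excess_bool(labels)
    n = y.size
    if zp.shape != (n,) or zs.shape != (n,):
        raise ValueError("z_primary, z_secondary and labels must have equal length")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to fit thresholds")

    order = np.argsort(zp, kind="stable")
    y_o = y[order]
    zs_o = zs[order]
    cuts_p = _candidate_cuts(zp)          # length P
    cuts_s = _candidate_cuts(zs)          # length S

    # rank boundaries: subjects with zp >= cuts_p[k] form the suffix [kpos[k], n)
    kpos = np.searchsorted(np.sort(zp), cuts_p, side="left")     # (P,)

    tot_e = int(y_o.sum())
    cum_e = np.concatenate(([0], np.cumsum(y_o)))                 # (n+1,)
    cum_d = np.concatenate(([0], np.cumsum(~y_o)))                # (n+1,)

    # correct-under-secondary prefix counts: G[r, t] = # of the first r subjects
    # (in zp order) that secondary cut t classifies correctly
    sec_excess = zs_o[:, None] >= cuts_s[None, :]                 # (n, S)
    correct_sec = np.where(y_o[:, None], sec_excess, ~sec_excess)
    G = np.vstack([np.zeros((1, cuts_s.size), dtype=int),
                   np.cumsum(correct_sec, axis=0)])               # (n+1, S)
    # predicted-excess-under-secondary prefix counts (for confusion assembly)
    E2 = np.vstack([np.zeros((1, cuts_s.size), dtype=int),
                    np.cumsum(sec_excess & y_o[:, None], axis=0)])
    P2 = np.vstack([np.zeros((1, cuts_s.size), dtype=int),
                    np.cumsum(sec_excess, axis=0)])

    ka = kpos                                                      # alpha index a
    kb = kpos                                                      # beta index b
    # correct(b, a, t) = [tot_e − cum_e[ka]] + cum_d[kb] + G[ka, t] − G[kb, t]
    U = (tot_e - cum_e[ka])[:, None] + G[ka]                       # (P, S) — alpha part
    V = cum_d[kb][:, None] - G[kb]                                 # (P, S) — beta part
    correct = V[:, None, :] + U[None, :, :]                        # (b, a, t)
    # enforce alpha >= beta i.e. ka >= kb (cuts are increasing)
    invalid = kpos[:, None] > kpos[None, :]                        # (b, a)
    correct = np.where(invalid[:, :, None], -1, correct)

    best = correct.max()
    tie_b, tie_a, tie_t = np.nonzero(correct == best)

    # MCC tie-break: assemble confusion counts for every tied candidate
    a_k, b_k = kpos[tie_a], kpos[tie_b]
    tp_e = (tot_e - cum_e[a_k]) + (E2[a_k, tie_t] - E2[b_k, tie_t])   # excess pred excess
    pred_e = (y_o.size - a_k) + (P2[a_k, tie_t] - P2[b_k, tie_t])
    fn_e = tot_e - tp_e                    # excess predicted deficient
    fp_e = pred_e - tp_e                   # deficient predicted excess
    tn_e = (n - tot_e) - fp_e
    mccs = _mcc_from_counts(tp_e, fn_e, fp_e, tn_e)
    band = cuts_p[tie_a] - cuts_p[tie_b]
    band = np.where(np.isfinite(band), band, np.inf)
    band[cuts_p[tie_a] == cuts_p[tie_b]] = 0.0
    # lexicographic: max mcc, then min band, then scan order
    key = np.lexsort((tie_t, tie_a, tie_b, band, -mccs))
    pick = key[0]

    model = MixedThresholdModel(
        primary=ThresholdRule(primary_name, float(cuts_p[tie_a[pick]]),
                              float(cuts_p[tie_b[pick]])),
        secondary=ThresholdRule(secondary_name, float(cuts_s[tie_t[pick]]),
                                float(cuts_s[tie_t[pick]])),
    )
    return ThresholdFit(model=model,
                        training_accuracy=float(best) / n,
                        training_mcc=float(mccs[pick]),
                        n=n)


def fit_single_threshold(z, labels, variable_name: str = "PP_avg") -> ThresholdFit:
    """Best single cut (α = β) on one standardized variable.

    Same objective and tie-breaks as :func:`fit_thresholds` restricted to the
    degenerate band.
    """
    z = np.asarray(z, dtype=float)
    y = _as_excess_bool(labels)
    n = y.size
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to fit a threshold")
    cuts = _candidate_cuts(z)
    k = np.searchsorted(np.sort(z), cuts, side="left")
    tot_e = int(y.sum())
    order = np.argsort(z, kind="stable")
    cum_e = np.concatenate(([0], np.cumsum(y[order])))
    cum_d = np.concatenate(([0], np.cumsum(~y[order])))
    correct = (tot_e - cum_e[k]) + cum_d[k]
    best = correct.max()
    ties = np.nonzero(correct == best)[0]
    tp_e = tot_e - cum_e[k[ties]]
    fp_e = (n - k[ties]) - tp_e
    fn_e = tot_e - tp_e
    tn_e = (n - tot_e) - fp_e
    mccs = _mcc_from_counts(tp_e, fn_e, fp_e, tn_e)
    pick = ties[np.lexsort((ties, -mccs))[0]]
    cut = float(cuts[pick])
    model = MixedThresholdModel(
        primary=ThresholdRule(variable_name, cut, cut),
        secondary=ThresholdRule(variable_name, cut, cut),
    )
    return ThresholdFit(model=model, training_accuracy=float(best) / n,
                        training_mcc=float(mccs[np.nonzero(ties == pick)[0][0]]), n=n)


def _as_excess_bool(labels) -> np.ndarray:
    arr = np.asarray(list(labels))
    bad = set(arr.tolist()) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return arr == EXCESS


class SingleThreshold:
    """Model object for the degenerate one-variable rule (α = β).

    Standardization statistics are estimated from the training cohort and
    stored, mirroring :class:`MixedThreshold`.
    """

    def __init__(self, x, labels, variable_name: str = "PP_avg"):
        self.x = np.asarray(x, dtype=float)
        self.labels = list(labels)
        self.variable_name = variable_name

    def fit(self) -> "SingleThresholdResults":
        m, s = self.x.mean(), self.x.std(ddof=1)
        if s == 0:
            raise ValueError("zero variance in the threshold variable")
        fit = fit_single_threshold((self.x - m) / s, self.labels,
                                   variable_name=self.variable_name)
        return SingleThresholdResults(fit, (m, s))


class SingleThresholdResults:
    def __init__(self, fit: ThresholdFit, moments: tuple[float, float]):
        self.rule = fit.model.primary
        self.training_accuracy = fit.training_accuracy
        self.training_mcc = fit.training_mcc
        self.nobs = fit.n
        self.moments = moments

    def predict(self, x) -> list[str]:
        m, s = self.moments
        z = (np.asarray(x, float).ravel() - m) / s
        return [EXCESS if v >= self.rule.alpha else DEFICIENT for v in z]


class MixedThreshold:
    """Model object for the sequential two-variable classifier.

    Parameters
    ----------
    z_primary, z_secondary : array-like
        Raw (unstandardized) cohort values of the primary and secondary pulse
        quantities; standardization statistics are estimated here and stored,
        so held-out subjects can be scored on the training scale.
    labels : sequence of {"deficient", "excess"}
    """

    def __init__(self, z_primary, z_secondary, labels,
                 primary_name: str = "PP_avg", secondary_name: str = "PP_max"):
        self.x_primary = np.asarray(z_primary, dtype=float)
        self.x_secondary = np.asarray(z_secondary, dtype=float)
        self.labels = list(labels)
        self.primary_name = primary_name
        self.secondary_name = secondary_name

    @classmethod
    def from_dataframe(cls, df, primary: str = "PP_avg", secondary: str = "PP_max",
                       label_col: str = "label") -> "MixedThreshold":
        return cls(df[primary].to_numpy(), df[secondary].to_numpy(),
                   df[label_col], primary_name=primary, secondary_name=secondary)

    def fit(self) -> "MixedThresholdResults":
        mp, sp = self.x_primary.mean(), self.x_primary.std(ddof=1)
        ms, ss = self.x_secondary.mean(), self.x_secondary.std(ddof=1)
        if sp == 0 or ss == 0:
            raise ValueError("zero variance in a threshold variable")
        zp = (self.x_primary - mp) / sp
        zs = (self.x_secondary - ms) / ss
        fit = fit_thresholds(zp, zs, self.labels,
                             primary_name=self.primary_name,
                             secondary_name=self.secondary_name)
        return MixedThresholdResults(self, fit, (mp, sp), (ms, ss))


class MixedThresholdResults:
    """Fitted sequential classifier with its standardization statistics."""

    def __init__(self, model: MixedThreshold, fit: ThresholdFit,
                 primary_moments: tuple[float, float],
                 secondary_moments: tuple[float, float]):
        self.model = model
        self.rule = fit.model
        self.training_accuracy = fit.training_accuracy
        self.training_mcc = fit.training_mcc
        self.nobs = fit.n
        self.primary_moments = primary_moments
        self.secondary_moments = secondary_moments

    def predict(self, x_primary, x_secondary) -> list[str]:
        mp, sp = self.primary_moments
        ms, ss = self.secondary_moments
        zp = (np.asarray(x_primary, float) - mp) / sp
        zs = (np.asarray(x_secondary, float) - ms) / ss
        return predict_mixed(zp, zs, self.rule)

    def to_json(self) -> str:
        d = self.rule.to_dict()
        d["standardization"] = {
            "primary": {"mean": self.primary_moments[0], "sd": self.primary_moments[1]},
            "secondary": {"mean": self.secondary_moments[0], "sd": self.secondary_moments[1]},
        }
        d["training"] = {"accuracy": self.training_accuracy, "mcc": self.training_mcc,
                         "n": self.nobs}
        return json.dumps(d, indent=2)

    def summary(self) -> str:
        r = self.rule
        lines = [
            "Mixed-variable sequential threshold model",
            "=" * 45,
            f"primary   : {r.primary.variable_name}  alpha={r.primary.alpha:+.4f}  "
            f"beta={r.primary.beta:+.4f}",
            f"secondary : {r.secondary.variable_name}  gamma=delta={r.secondary.alpha:+.4f}",
            f"n={self.nobs}  training accuracy={self.training_accuracy:.1%}  "
            f"MCC={self.training_mcc:.2f}",
        ]
        return "\n".join(lines)
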