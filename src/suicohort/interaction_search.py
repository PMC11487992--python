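"""Heuristic interaction search for logistic risk models.

The algorithm discovers conjunction features ("interactions of
interest") for a logistic regression in three phases while keeping the
final inference honest:

1.  *Preparation* — the data are split at random into a primary training
    set (40% of the total), a control set (10%) and a validation set
    (50%); the validation half is never touched before the final fit.
2.  *Search* — starting from the base model (main-effect dummies), every
    eligible conjunction of 2-3 variable levels is scored on the primary
    training set by the likelihood-ratio statistic of adding it to the
    current model.  The top-scoring candidate above a threshold T is
    tentatively added and recorded in the considered list L; if the
    enlarged model does not improve the held-out log-likelihood on the
    control set, it is rolled back (but stays in L, so it is never
    scored again).
3.  *Estimation* — the base terms plus the accepted features are refit
    once on the untouched validation set, so the reported coefficients,
    t-statistics and Wald intervals carry no selection bias.

Candidate conjunctions may involve reference levels (e.g. "male +
high"): an interaction feature is an indicator, not a product of
non-reference dummies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from itertools import combinations, product
from scipy.stats import chi2, norm

from .coding import CodingError
from .cohort import LEVEL_TO_VAR, term_indicator
from .univariate import Z_95, FittedModel, fit_logistic, log_likelihood, wald_ci

logger = logging.getLogger(__name__)

__all__ = [
    "VAR_ORDER",
    "DEFAULT_VARIABLES",
    "BASE_TERMS",
    "LeakageError",
    "SplitBundle",
    "InteractionFeature",
    "SearchConfig",
    "SearchState",
    "ValidationReport",
    "split_data",
    "enumerate_candidates",
    "score_candidate",
    "control_improves",
    "phase1_search",
    "phase2_estimate",
    "InteractionSearchLogit",
    "InteractionSearchResults",
]

#: Fixed variable order used for canonical feature names.
VAR_ORDER: tuple[str, ...] = ("gender", "age_band_ml", "risk", "era")

#: Study variables with ordered levels, reference level first.
DEFAULT_VARIABLES: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "age_band_ml": ("<18", "18-20", "21+"),
    "risk": ("low", "moderate", "high"),
    "era": ("pre_corona", "corona"),
}

#: Non-reference main-effect dummies of the base model.
BASE_TERMS: tuple[str, ...] = ("female", "18-20", "21+", "moderate", "high", "corona")


class LeakageError(RuntimeError):
    """Validation records were seen during the search phase."""


@dataclass(frozen=True)
class InteractionFeature:
    """A conjunction of (variable, level) assignments over 2-3 distinct
    variables; its indicator is 1 iff every assignment matches."""

    assignments: tuple[tuple[str, str], ...]

    def __post_init__(self):
        variables = [v for v, _ in self.assignments]
        if len(set(variables)) != len(variables):
            raise ValueError("at most one level per variable")
        if len(variables) < 2:
            raise ValueError("an interaction needs at least 2 variables")
        ordered = tuple(
            sorted(self.assignments, key=lambda a: VAR_ORDER.index(a[0]))
        )
        object.__setattr__(self, "assignments", ordered)

    @property
    def order(self) -> int:
        return len(self.assignments)

    @property
    def name(self) -> str:
        return " + ".join(level for _, level in self.assignments)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(v for v, _ in self.assignments)

    def indicator(self, coded: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(coded))
        for var, level in self.assignments:
            out *= (coded[var] == level).to_numpy(dtype=float)
        return out


@dataclass
class SearchConfig:
    """Tunables of the interaction search."""

    threshold: float = 10.828  # chi-square(1) upper 0.1% point
    max_order: int = 3
    min_count: int = 30  # sparse-cell guard on the primary training set
    fractions: tuple[float, float, float] = (0.4, 0.1, 0.5)
    seed: int = 0
    scoring_rule: str = "likelihood_ratio"
    improvement_metric: str = "control_log_likelihood"

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold T must be positive")
        if self.max_order < 2:
            raise ValueError("max interaction order must be >= 2")

    @property
    def candidate_alpha(self) -> float:
        """Per-candidate tail probability equivalent of T under the
        chi-square(1) reference distribution."""
        return float(chi2.sf(self.threshold, df=1))


@dataclass
class SplitBundle:
    """Disjoint primary-training / control / validation record sets."""

    primary_training: pd.DataFrame
    control: pd.DataFrame
    validation: pd.DataFrame
    seed: int
    fractions: tuple[float, float, float]

    def check_partition(self, n_total: int) -> None:
        idx = [set(d.index) for d in
               (self.primary_training, self.control, self.validation)]
        union = set().union(*idx)
        if sum(len(s) for s in idx) != len(union) or len(union) != n_total:
            raise LeakageError("splits are not a disjoint partition of the input")


def split_data(
    records: pd.DataFrame,
    seed: int,
    fractions: tuple[float, float, float] = (0.4, 0.1, 0.5),
) -> SplitBundle:
    """Uniform random partition (no stratification) into primary
    training, control and validation sets, with largest-remainder
    rounding so sizes are within one record of the exact fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    exact = np.array(fractions) * n
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for k in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[k] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    stops = np.cumsum(sizes)
    parts = [
        records.iloc[np.sort(perm[start:stop])]
        for start, stop in zip((0, *stops[:-1]), stops)
    ]
    bundle = SplitBundle(parts[0], parts[1], parts[2], seed, tuple(fractions))
    bundle.check_partition(n)
    return bundle


@dataclass
class SearchState:
    """Running state of the phase-1 search."""

    accepted: list[InteractionFeature] = field(default_factory=list)
    considered: list[str] = field(default_factory=list)  # the list L
    log: list[dict] = field(default_factory=list)
    restricted: bool = False
    base_fit: FittedModel | None = None
    final_fit: FittedModel | None = None

    @property
    def model_variables(self) -> frozenset[str]:
        """Variables appearing in the current model (all base variables
        plus those of accepted features)."""
        out = set(self._base_variables)
        for f in self.accepted:
            out |= f.variables
        return frozenset(out)

    _base_variables: tuple[str, ...] = tuple(DEFAULT_VARIABLES)


def enumerate_candidates(
    state: SearchState,
    variables: dict[str, tuple[str, ...]],
    config: SearchConfig,
    primary_training: pd.DataFrame,
) -> list[InteractionFeature]:
    """All order-2..max_order conjunctions of level assignments over
    distinct variables (reference levels included), minus features
    already in L and features with fewer than ``min_count`` positive
    indicators in the primary training set."""
    considered = set(state.considered)
    out = []
    names = [v for v in VAR_ORDER if v in variables]
    names += [v for v in variables if v not in VAR_ORDER]
    for order in range(2, config.max_order + 1):
        for combo in combinations(names, order):
            for levels in product(*(variables[v] for v in combo)):
                feat = InteractionFeature(tuple(zip(combo, levels)))
                if feat.name in considered:
                    continue
                if feat.indicator(primary_training).sum() < config.min_count:
                    continue
                out.append(feat)
    return out


def _design(
    coded: pd.DataFrame,
    base_terms: tuple[str, ...],
    features: list[InteractionFeature],
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(len(coded))]
    terms = ["intercept"]
    for t in base_terms:
        cols.append(term_indicator(t, coded))
        terms.append(t)
    for f in features:
        cols.append(f.indicator(coded))
        terms.append(f.name)
    return np.column_stack(cols), tuple(terms)


def score_candidate(
    current_fit: FittedModel,
    X_current: np.ndarray,
    feature_col: np.ndarray,
    y: np.ndarray,
) -> tuple[float, FittedModel | None]:
    """Likelihood-ratio statistic 2*(ll(model + feature) - ll(model))
    from two maximum-likelihood fits on the primary training set.

    The augmented fit is warm-started from the current parameters; a
    non-converging augmented fit scores 0 with a logged warning.
    """
    X_aug = np.column_stack([X_current, feature_col])
    start = np.append(current_fit.params, 0.0)
    try:
        aug = fit_logistic(X_aug, y, ridge=1e-8, start=start)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("augmented fit failed (%s); scoring 0", exc)
        return 0.0, None
    if not aug.converged:
        logger.warning("augmented fit did not converge; scoring 0")
        return 0.0, None
    return max(0.0, 2.0 * (aug.llf - current_fit.llf)), aug


def control_improves(
    model_with: FittedModel,
    model_without: FittedModel,
    X_control_with: np.ndarray,
    X_control_without: np.ndarray,
    y_control: np.ndarray,
) -> bool:
    """True iff the with-feature model's total log-likelihood on the
    held-out control records strictly exceeds the without-feature one."""
    ll_with = log_likelihood(model_with.params, X_control_with, y_control)
    ll_without = log_likelihood(model_without.params, X_control_without, y_control)
    return ll_with > ll_without


def phase1_search(
    bundle: SplitBundle,
    outcome: str,
    config: SearchConfig | None = None,
    variables: dict[str, tuple[str, ...]] | None = None,
    base_terms: tuple[str, ...] = BASE_TERMS,
) -> SearchState:
    """Iterative forward search for interaction features.

    Each round scores every eligible candidate on the primary training
    set, takes the maximum (ties broken by lower order, then canonical
    name), and if it exceeds T adds it to the model and to L; the
    control set then vetoes additions that do not improve held-out fit
    (vetoed features stay in L and are never re-scored).  After a veto,
    enumeration is restricted to interactions among variables already in
    the model.  Terminates when no candidate clears T or none remain.
    """
    config = config or SearchConfig()
    variables = variables or DEFAULT_VARIABLES
    state = SearchState(_base_variables=tuple(variables))
    train = bundle.primary_training
    ctrl = bundle.control
    y_train = train[outcome].to_numpy(dtype=float)
    y_ctrl = ctrl[outcome].to_numpy(dtype=float)

    X_train, terms = _design(train, base_terms, [])
    X_ctrl, _ = _design(ctrl, base_terms, [])
    current = fit_logistic(X_train, y_train, terms=terms, ridge=1e-8)
    state.base_fit = current

    iteration = 0
    while True:
        iteration += 1
        cands = enumerate_candidates(state, variables, config, train)
        if state.restricted:
            cands = [c for c in cands if c.variables <= state.model_variables]
        if not cands:
            state.log.append({"iteration": iteration, "n_candidates": 0,
                              "stop": "no eligible candidates"})
            break
        scored = []
        for feat in cands:
            col = feat.indicator(train)
            s, aug = score_candidate(current, X_train, col, y_train)
            scored.append((s, feat, aug, col))
        best_score, best, best_fit, best_col = max(
            scored, key=lambda t: (t[0], -t[1].order, _rev_name(t[1].name))
        )
        entry = {
            "iteration": iteration,
            "n_candidates": len(cands),
            "best": best.name,
            "score": float(best_score),
        }
        if best_score <= config.threshold or best_fit is None:
            entry["stop"] = "no candidate above threshold"
            state.log.append(entry)
            break
        state.considered.append(best.name)  # enters L whether kept or not
        X_aug = np.column_stack([X_train, best_col])
        X_ctrl_aug = np.column_stack([X_ctrl, best.indicator(ctrl)])
        improved = control_improves(best_fit, current, X_ctrl_aug, X_ctrl, y_ctrl)
        entry["control_improved"] = improved
        entry["accepted"] = improved
        if improved:
            state.accepted.append(best)
            current = best_fit
            X_train = X_aug
            X_ctrl = X_ctrl_aug
        else:
            state.restricted = True  # fall back to within-model variables
        entry["model_terms"] = list(base_terms) + [f.name for f in state.accepted]
        state.log.append(entry)
    state.final_fit = current
    return state


class _rev_name(str):
    """Inverted string ordering so a single max() keeps 'highest score,
    then lowest order, then lexicographically first name'."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


class ValidationReport:
    """Final-model estimates on the validation half.

    Rows: the intercept (full-population baseline, with the validation
    event count as n), each reference level (estimate 0, OR exactly 1),
    and each non-reference dummy / accepted feature with its estimate,
    t-statistic (estimate/SE) and Wald 95% CI for the odds ratio.
    """

    def __init__(self, fitted: FittedModel, frame: pd.DataFrame,
                 features: list[InteractionFeature]):
        self.fitted = fitted
        self.frame = frame
        self.features = features

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def summary(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["OR (95% CI)"] = [
            "1 (1, 1)" if ref else f"{o:.2f} ({lo:.2f}, {hi:.2f})"
            for ref, o, lo, hi in zip(
                out["reference"], out["odds_ratio"], out["ci_low"], out["ci_high"]
            )
        ]
        return out[["term", "n", "estimate", "t", "OR (95% CI)"]]


def phase2_estimate(
    bundle: SplitBundle,
    accepted: list[InteractionFeature],
    outcome: str,
    variables: dict[str, tuple[str, ...]] | None = None,
    base_terms: tuple[str, ...] = BASE_TERMS,
) -> ValidationReport:
    """Single maximum-likelihood fit of base dummies + accepted features
    on the validation records only.

    Raises :class:`LeakageError` if any validation record also appears
    in the primary training or control sets.
    """
    variables = variables or DEFAULT_VARIABLES
    seen = set(bundle.primary_training.index) | set(bundle.control.index)
    if seen & set(bundle.validation.index):
        raise LeakageError("validation records overlap the training half")
    val = bundle.validation
    y = val[outcome].to_numpy(dtype=float)
    X, terms = _design(val, base_terms, accepted)
    fitted = fit_logistic(X, y, terms=terms, ridge=1e-8)
    se = fitted.bse
    by_term = {t: i for i, t in enumerate(terms)}

    b0, s0 = float(fitted.params[0]), float(se[0])
    lo0, hi0 = wald_ci(b0, s0)
    rows = [{
        "term": "B0 (full population)",
        "n": int(y.sum()),
        "estimate": b0,
        "t": b0 / s0,
        "odds_ratio": float(np.exp(b0)),
        "ci_low": lo0,
        "ci_high": hi0,
        "p_value": float(2 * norm.sf(abs(b0 / s0))),
        "reference": False,
    }]
    for var in variables:
        ref = variables[var][0]
        rows.append({
            "term": ref,
            "n": int((val[var] == ref).sum()),
            "estimate": 0.0, "t": np.nan,
            "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
            "p_value": np.nan, "reference": True,
        })
    items = [(t, term_indicator(t, val)) for t in base_terms]
    items += [(f.name, f.indicator(val)) for f in accepted]
    for name, col in items:
        j = by_term[name]
        b, s = float(fitted.params[j]), float(se[j])
        lo, hi = wald_ci(b, s)
        rows.append({
            "term": name,
            "n": int(col.sum()),
            "estimate": b,
            "t": b / s,
            "odds_ratio": float(np.exp(b)),
            "ci_low": lo,
            "ci_high": hi,
            "p_value": float(2 * norm.sf(abs(b / s))),
            "reference": False,
        })
    return ValidationReport(fitted, pd.DataFrame(rows), accepted)


class InteractionSearchLogit:
    """Three-phase interaction-search logistic model.

    Parameters
    ----------
    data : coded records, complete on ``variables`` and ``outcome``
        (rows with missing values are dropped here).
    outcome : boolean column, e.g. "si" or "sa".
    variables : ordered level maps, reference level first.
    config : :class:`SearchConfig`.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 variables: dict[str, tuple[str, ...]] | None = None,
                 config: SearchConfig | None = None):
        self.outcome = outcome
        self.variables = variables or DEFAULT_VARIABLES
        self.config = config or SearchConfig()
        needed = [*self.variables, outcome]
        self.data = data.dropna(subset=needed)
        for var, levels in self.variables.items():
            undeclared = set(self.data[var].unique()) - set(levels)
            if undeclared:
                raise CodingError(f"undeclared level(s) {sorted(undeclared)} in {var}")

    def fit(self, seed: int | None = None) -> "InteractionSearchResults":
        seed = self.config.seed if seed is None else seed
        base_terms = tuple(
            lvl for var, levels in self.variables.items() for lvl in levels[1:]
        )
        bundle = split_data(self.data, seed, self.config.fractions)
        state = phase1_search(bundle, self.outcome, self.config,
                              self.variables, base_terms)
        report = phase2_estimate(bundle, state.accepted, self.outcome,
                                 self.variables, base_terms)
        return InteractionSearchResults(self, bundle, state, report)


class InteractionSearchResults:
    """Search trace plus the validation-set estimates."""

    def __init__(self, model: InteractionSearchLogit, bundle: SplitBundle,
                 state: SearchState, report: ValidationReport):
        self.model = model
        self.bundle = bundle
        self.state = state
        self.report = report

    @property
    def accepted_features(self) -> list[InteractionFeature]:
        return list(self.state.accepted)

    @property
    def considered(self) -> list[str]:
        return list(self.state.considered)

    def summary(self) -> pd.DataFrame:
        return self.report.summary()
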