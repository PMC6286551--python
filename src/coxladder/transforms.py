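"""Predictor codings: cut-point categories, fractional polynomials, splines.

Three ways of carrying a continuous clinical covariate into a Cox
model, in increasing order of flexibility:

* :class:`CategoryScheme` — classic cut-point categorization (e.g. the
  T1/T2/T3 tumor-size classes), entered as dummy indicators;
* :class:`FPSpec` — fractional polynomials x^p with powers from the
  conventional candidate set {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (x^0 read
  as ln x), degree 1 or 2, selected by a closed likelihood-ratio test
  procedure that only admits extra flexibility when the fit improves
  significantly; :func:`mfp_fit` runs the multivariable backfitting
  version of that selection;
* :class:`RCSSpec` — restricted cubic splines: piecewise cubics with
  k knots, constrained to be linear beyond the boundary knots, spanned
  by k-1 basis columns.

Every spec serializes to a plain dict (JSON-friendly) so a model fitted
on one cohort can be re-applied bit-identically to another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from coxladder.survival_core import cox_fit

#: Conventional fractional-polynomial candidate powers.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


# ---------------------------------------------------------------------------
# cut-point categorization

@dataclass(frozen=True)
class CategoryScheme:
    """Ordered cut-points with a per-cut boundary convention.

    ``right_closed[i]`` True means values equal to ``cut_points[i]``
    fall in the lower category (an "x <= c" boundary); False means they
    fall in the upper one ("x < c").  The clinical conventions differ
    by factor — age 35 belongs with the older group while size 20 mm is
    still T1 — so the flag is explicit per cut.
    """

    covariate: str
    cut_points: tuple[float, ...]
    right_closed: tuple[bool, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if list(self.cut_points) != sorted(set(self.cut_points)):
            raise ValueError("cut_points must be strictly increasing")
        if len(self.labels) != len(self.cut_points) + 1:
            raise ValueError("need n_cuts + 1 labels")
        if len(self.right_closed) != len(self.cut_points):
            raise ValueError("need one boundary convention per cut")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    @property
    def n_cols(self) -> int:
        return self.n_categories - 1

    def assign(self, x) -> np.ndarray:
        """Category index (0-based) for each value; partitions the domain."""
        x = np.asarray(x, dtype=float)
        if self.covariate in ("tumor_size_mm", "n_pos_nodes") and np.any(x < 0):
            raise ValueError(f"negative {self.covariate} outside domain")
        idx = np.zeros(x.shape, dtype=int)
        for cut, closed in zip(self.cut_points, self.right_closed):
            idx += (x > cut) if closed else (x >= cut)
        return idx

    def basis(self, x) -> np.ndarray:
        """Dummy indicator columns for categories 1..k-1 (0 is reference)."""
        idx = self.assign(x)
        return (idx[:, None] == np.arange(1, self.n_categories)[None, :]).astype(float)

    def to_dict(self) -> dict:
        return {
            "type": "category",
            "covariate": self.covariate,
            "cut_points": list(self.cut_points),
            "right_closed": list(self.right_closed),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryScheme":
        return cls(d["covariate"], tuple(d["cut_points"]),
                   tuple(bool(b) for b in d["right_closed"]), tuple(d["labels"]))


def categorize(x, scheme: CategoryScheme) -> np.ndarray:
    """Category index for ``x`` under ``scheme`` (vectorized)."""
    return scheme.assign(x)


def dichotomized_scheme(covariate: str) -> CategoryScheme:
    """Single clinical cut-point: age <35 vs >=35, size >20 vs <=20 mm,
    any positive nodes vs none."""
    table = {
        "age_years": ((35.0,), (False,), ("<35", ">=35")),
        "tumor_size_mm": ((20.0,), (True,), ("<=20mm", ">20mm")),
        "n_pos_nodes": ((0.0,), (True,), ("N0", "N+")),
    }
    return CategoryScheme(covariate, *table[covariate])


def categorized_scheme(covariate: str) -> CategoryScheme:
    """Three or four clinical classes: age <35 / 35-50 / >50, tumor size
    T1 (<=20) / T2 (21-50) / T3 (>50), nodes N0 / N1-3 / N4-9 / N10+."""
    table = {
        "age_years": ((35.0, 50.0), (False, True), ("<35", "35-50", ">50")),
        "tumor_size_mm": ((20.0, 50.0), (True, True), ("T1", "T2", "T3")),
        "n_pos_nodes": ((0.0, 3.0, 9.0), (True, True, True),
                        ("N0", "N1-3", "N4-9", "N10+")),
    }
    return CategoryScheme(covariate, *table[covariate])


# ---------------------------------------------------------------------------
# fractional polynomials

@dataclass(frozen=True)
class FPSpec:
    """A fractional-polynomial coding of one covariate.

    Columns are powers of z = (x + shift) / scale with z^0 read as
    ln z; a repeated power (p, p) contributes z^p and z^p * ln z.
    ``powers = (1,)`` is the plain linear coding; an empty tuple marks
    a covariate excluded by the selection procedure.
    """

    covariate: str
    powers: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if len(self.powers) > 2:
            raise ValueError("fractional polynomials of degree > 2 not supported")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def degree(self) -> int:
        return len(self.powers)

    @property
    def is_linear(self) -> bool:
        return self.powers == (1.0,)

    @property
    def n_cols(self) -> int:
        return len(self.powers)

    def basis(self, x) -> np.ndarray:
        return fp_basis(x, self)

    def to_dict(self) -> dict:
        return {"type": "fp", "covariate": self.covariate,
                "powers": list(self.powers), "shift": self.shift,
                "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "FPSpec":
        return cls(d["covariate"], tuple(d["powers"]), d["shift"], d["scale"])


def fp_shift_scale(x) -> tuple[float, float]:
    """Preliminary shift and scale for an FP coding of observed ``x``.

    If any value is non-positive the shift is the smallest positive
    increment between distinct observed values (1 for integer counts);
    the scale is the power of ten that brings the shifted range near
    unity, which keeps z^3 and z^-2 numerically tame.
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("need at least two distinct values")
    shift = 0.0
    if distinct[0] <= 0:
        shift = float(np.min(np.diff(distinct))) - float(distinct[0]) \
            if distinct[0] < 0 else float(np.min(np.diff(distinct)))
    rng = float(distinct[-1] - distinct[0])
    scale = 10.0 ** np.floor(np.log10(rng)) if rng > 0 else 1.0
    return shift, float(scale)


def fp_basis(x, spec: FPSpec) -> np.ndarray:
    """Evaluate the FP basis columns; requires x + shift > 0."""
    x = np.asarray(x, dtype=float)
    z = (x + spec.shift) / spec.scale
    if np.any(z <= 0):
        raise ValueError("non-positive argument after shift; adjust FPSpec.shift")
    logz = np.log(z)

    def one(p):
        return logz if p == 0 else z**p

    if spec.degree == 0:
        return np.empty((x.size, 0))
    if spec.degree == 1:
        return one(spec.powers[0])[:, None]
    p1, p2 = spec.powers
    c1 = one(p1)
    c2 = c1 * logz if p1 == p2 else one(p2)
    return np.column_stack([c1, c2])


@dataclass
class FPSelectionReport:
    """Closed-test audit trail: log-likelihoods and the decision path."""

    covariate: str
    ll_null: float
    ll_linear: float
    best_fp1: tuple[float, ...]
    ll_fp1: float
    best_fp2: tuple[float, ...] | None
    ll_fp2: float | None
    p_any: float | None      # most complex FP vs null
    p_nonlinear: float | None  # most complex FP vs linear
    p_fp2_vs_fp1: float | None
    selected: "FPSpec" = None


def _lr_p(ll1, ll0, df):
    return float(stats.chi2.sf(max(0.0, 2.0 * (ll1 - ll0)), df))


def select_fp(
    x,
    time,
    event,
    strata=None,
    alpha: float = 0.05,
    covariate: str = "x",
    adjust=None,
    max_degree: int = 2,
    forced: bool = True,
    ties: str = "breslow",
    return_report: bool = False,
):
    """Closed-test function selection for one covariate.

    The most complex candidate (best FP2 over the candidate powers, or
    best FP1 when ``max_degree=1``) is compared in sequence against the
    null model (4 df; skipped when the covariate is ``forced`` into the
    model), the linear coding (3 df) and the best FP1 (2 df), each at
    level ``alpha``; the first non-significant step stops and returns
    the simpler form.  "Best" means maximum stratified Cox partial
    likelihood; ``adjust`` columns (other covariates' current codings)
    are included in every fit.

    Returns the selected :class:`FPSpec` (optionally with a
    :class:`FPSelectionReport`).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if max_degree not in (1, 2):
        raise ValueError("max_degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    if int(np.asarray(event).sum()) <= 2 * max_degree:
        raise ValueError("fewer events than degrees of freedom under test")
    shift, scale = fp_shift_scale(x)
    adj = (np.empty((x.size, 0)) if adjust is None
           else np.atleast_2d(np.asarray(adjust, dtype=float)))

    def ll_of(powers) -> float:
        spec = FPSpec(covariate, powers, shift, scale)
        design = np.column_stack([spec.basis(x), adj]) if powers else adj
        return cox_fit(design, time, event, strata, ties=ties).log_partial_likelihood

    ll_null = ll_of(())
    ll_linear = ll_of((1.0,))
    fp1 = {(p,): ll_of((p,)) for p in FP_POWERS}
    best1 = max(fp1, key=fp1.get)
    ll1 = fp1[best1]
    if max_degree == 2:
        fp2 = {pair: ll_of(pair)
               for pair in itertools.combinations_with_replacement(FP_POWERS, 2)}
        best2 = max(fp2, key=fp2.get)
        ll2 = fp2[best2]
        ll_top, top_powers, top_df = ll2, best2, 4
    else:
        fp2, best2, ll2 = None, None, None
        ll_top, top_powers, top_df = ll1, best1, 2

    p_any = p_nonlin = p_21 = None
    if not forced:
        p_any = _lr_p(ll_top, ll_null, top_df)
        if p_any >= alpha:
            selected = FPSpec(covariate, (), shift, scale)
            return _sel_result(selected, covariate, ll_null, ll_linear, best1, ll1,
                               best2, ll2, p_any, p_nonlin, p_21, return_report)
    p_nonlin = _lr_p(ll_top, ll_linear, top_df - 1)
    if p_nonlin >= alpha:
        selected = FPSpec(covariate, (1.0,), shift, scale)
    elif max_degree == 1:
        selected = FPSpec(covariate, best1, shift, scale)
    else:
        p_21 = _lr_p(ll2, ll1, 2)
        powers = best2 if p_21 < alpha else best1
        selected = FPSpec(covariate, powers, shift, scale)
    return _sel_result(selected, covariate, ll_null, ll_linear, best1, ll1,
                       best2, ll2, p_any, p_nonlin, p_21, return_report)


def _sel_result(selected, covariate, ll_null, ll_linear, best1, ll1, best2, ll2,
                p_any, p_nonlin, p_21, return_report):
    if not return_report:
        return selected
    return selected, FPSelectionReport(covariate, ll_null, ll_linear, best1, ll1,
                                       best2, ll2, p_any, p_nonlin, p_21, selected)


# ---------------------------------------------------------------------------
# restricted cubic splines

@dataclass(frozen=True)
class RCSSpec:
    """Restricted cubic spline: k knots, k-1 basis columns.

    The first column is x itself; the remaining k-2 are the standard
    restricted truncated-power terms, normalized by the squared span of
    the boundary knots, so any fitted linear combination is linear
    outside the boundary knots by construction.
    """

    covariate: str
    knots: tuple[float, ...]

    def __post_init__(self):
        if len(self.knots) < 3:
            raise ValueError("restricted cubic splines need k >= 3 knots")
        if list(self.knots) != sorted(set(self.knots)):
            raise ValueError("knots must be strictly increasing (no duplicates)")

    @property
    def basis_dim(self) -> int:
        return len(self.knots) - 1

    @property
    def n_cols(self) -> int:
        return self.basis_dim

    def basis(self, x) -> np.ndarray:
        return rcs_basis(x, self)

    def to_dict(self) -> dict:
        return {"type": "rcs", "covariate": self.covariate,
                "knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "RCSSpec":
        return cls(d["covariate"], tuple(d["knots"]))


def rcs_basis(x, spec: RCSSpec) -> np.ndarray:
    """Evaluate the restricted truncated-power basis at ``x``."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots, dtype=float)
    k = t.size
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (cube(x - t[j])
                - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def nearest_rank_percentile(x, q) -> np.ndarray:
    """Nearest-rank empirical percentile(s): smallest observed value with
    at least q% of the sample at or below it."""
    x = np.sort(np.asarray(x, dtype=float))
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q <= 0) | (q > 100)):
        raise ValueError("percentiles must lie in (0, 100]")
    ranks = np.ceil(q / 100.0 * x.size).astype(int) - 1
    out = x[np.clip(ranks, 0, x.size - 1)]
    return out if out.size > 1 else float(out[0])

#: Harrell's recommended percentile locations for five knots.
KNOT_PERCENTILES = (5.0, 27.5, 50.0, 72.5, 95.0)

#: Fixed knots for the positive-node count (almost 40 % zeros, so
#: percentile placement degenerates).
NODE_KNOTS = (1.0, 2.0, 3.0, 4.0, 10.0)


def place_knots(x, covariate: str) -> RCSSpec:
    """Five knots: percentile-placed for age and size, fixed for nodes.

    Ages and sizes get knots at the 5th/27.5th/50th/72.5th/95th
    percentiles; the node count, dominated by zeros, gets fixed knots
    at 1, 2, 3, 4 and 10 positive nodes.
    """
    if covariate == "n_pos_nodes":
        return RCSSpec(covariate, NODE_KNOTS)
    knots = np.atleast_1d(nearest_rank_percentile(x, KNOT_PERCENTILES))
    if np.unique(knots).size < len(KNOT_PERCENTILES):
        raise ValueError(
            f"only {np.unique(knots).size} distinct percentile knots for "
            f"{covariate}; too few distinct values — consider fewer knots")
    return RCSSpec(covariate, tuple(float(k) for k in knots))


# ---------------------------------------------------------------------------
# multivariable FP backfitting

def mfp_fit(
    cohort,
    covariates=("age_years", "tumor_size_mm", "n_pos_nodes"),
    alpha: float = 0.05,
    stratified: bool = True,
    ties: str = "breslow",
    max_cycles: int = 5,
    forced: bool = True,
    max_degree: int = 2,
):
    """Multivariable fractional-polynomial selection by backfitting.

    Covariates are visited in decreasing order of significance of their
    linear coding in a joint linear-Cox fit; each in turn gets the
    closed-test selection of :func:`select_fp` adjusted for the current
    codings of the others; the cycle repeats until a full pass leaves
    every selected form unchanged (or a cycle guard triggers, which is
    logged with the cycle history).  The result is the final joint Cox
    fit of all selected bases packaged as a
    :class:`~coxladder.model.PrognosticModel`.

    With a single covariate this reduces exactly to :func:`select_fp`.
    """
    from coxladder.model import PrognosticModel
    from coxladder.survival_core import logger as _core_logger

    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    time = cohort["time_years"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=int)
    strata = cohort["stratum"].to_numpy() if stratified else None
    xs = {c: cohort[c].to_numpy(dtype=float) for c in covariates}

    current = {}
    for c in covariates:
        shift, scale = fp_shift_scale(xs[c])
        current[c] = FPSpec(c, (1.0,), shift, scale)

    def stacked(names):
        blocks = [current[c].basis(xs[c]) for c in names if current[c].degree]
        return (np.column_stack(blocks) if blocks
                else np.empty((time.size, 0)))

    # visiting order: decreasing significance of the linear coding
    joint = cox_fit(stacked(covariates), time, event, strata, ties=ties)
    slices, start = {}, 0
    for c in covariates:
        slices[c] = slice(start, start + current[c].n_cols)
        start += current[c].n_cols
    wald_p = {
        c: float(stats.chi2.sf(
            float(joint.coefficients[slices[c]]
                  @ np.linalg.solve(joint.covariance[slices[c], slices[c]],
                                    joint.coefficients[slices[c]])),
            df=current[c].n_cols))
        for c in covariates
    }
    order = sorted(covariates, key=lambda c: wald_p[c])

    history = []
    for cycle in range(1, max_cycles + 1):
        previous = dict(current)
        for c in order:
            others = [o for o in order if o != c]
            current[c] = select_fp(
                xs[c], time, event, strata, alpha=alpha, covariate=c,
                adjust=stacked(others), max_degree=max_degree,
                forced=forced, ties=ties)
        history.append({c: current[c].powers for c in order})
        if all(current[c] == previous[c] for c in covariates):
            break
    else:
        _core_logger.warning(
            "MFP backfitting did not stabilize in %d cycles; history: %s",
            max_cycles, history)

    design = stacked(covariates)
    fit = cox_fit(design, time, event, strata, ties=ties)
    transforms = {c: current[c] for c in covariates}
    return PrognosticModel(
        transforms=transforms,
        weights=fit.coefficients,
        covariance=fit.covariance,
        meta={
            "method": "mfp",
            "alpha": alpha,
            "order": order,
            "cycles": len(history),
            "history": [{c: list(p) for c, p in h.items()} for h in history],
            "log_partial_likelihood": fit.log_partial_likelihood,
            "n_events": fit.n_events,
            "stratified": stratified,
        },
    )


TRANSFORM_TYPES = {"category": CategoryScheme, "fp": FPSpec, "rcs": RCSSpec}


def transform_from_dict(d: dict):
    """Inverse of each spec's ``to_dict``; dispatches on the type tag."""
    try:
        cls = TRANSFORM_TYPES[d["type"]]
    except KeyError as exc:
        raise ValueError(f"unknown transform type {d.get('type')!r}") from exc
    return cls.from_dict(d)
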