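"""Extended-twin (ACTE) variance-components model, fit per edge.

The phenotype (one connectome edge per fit) decomposes into additive genetic
(A), shared environmental (C), twin-specific environmental (T) and unique
environmental + error (E) variance. Families contribute independent
multivariate-normal blocks

    y_f ~ N(X_f beta, sigma2_A K + sigma2_C J + sigma2_T Tm + sigma2_E I)

where K is the kinship matrix (MZ co-twins 1, DZ co-twins and sibling pairs
0.5, self 1), J is all ones, and Tm is 1 between co-twins and on their
diagonal positions (so T adds variance only to twins). The mean carries
intercept, age and sex effects. Estimation is maximum likelihood with beta
profiled out analytically; nonnegativity is enforced by parameterizing each
component as the square of an unconstrained scalar. Confidence intervals are
profile-likelihood intervals on the standardized-share scale, bounded where
the profiled deviance crosses the chi-square(1) critical value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .synthetic import TWIN_ROLES, Cohort

__all__ = [
    "FamilyStructure",
    "TwinDesign",
    "ACTEEstimate",
    "family_covariance",
    "build_design",
    "fit_acte",
    "acte_loglik",
    "profile_ci",
    "significant_a",
    "heritable_fraction",
]

COMPONENTS = ("A", "C", "T", "E")
MAX_FAMILY_SIZE = 4


@dataclass
class FamilyStructure:
    """Relationship matrices of one family (members in canonical order:
    the twin pair first, then siblings, each sorted by id)."""

    member_ids: list[str]
    roles: list[str]
    zygosity: str | None  # "MZ" | "DZ" | None
    kinship: np.ndarray  # K
    shared_env: np.ndarray  # J (all ones)
    twin: np.ndarray  # Tm

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _structure_matrices(roles: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = len(roles)
    is_twin = np.array([r in TWIN_ROLES for r in roles])
    k = np.full((m, m), 0.5)
    np.fill_diagonal(k, 1.0)
    if "MZ_twin" in roles:
        tw = np.flatnonzero(is_twin)
        for i in tw:
            for j in tw:
                k[i, j] = 1.0
    j = np.ones((m, m))
    tm = np.outer(is_twin, is_twin).astype(float)
    return k, j, tm


def family_structure(members) -> FamilyStructure:
    """Build the relationship matrices for one family's subjects."""
    if not 2 <= len(members) <= MAX_FAMILY_SIZE:
        raise ValueError(f"family size must be 2-{MAX_FAMILY_SIZE}")
    ordered = sorted(members, key=lambda s: (s.role not in TWIN_ROLES, s.subject_id))
    roles = [s.role for s in ordered]
    k, j, tm = _structure_matrices(roles)
    zyg = None
    if "MZ_twin" in roles:
        zyg = "MZ"
    elif "DZ_twin" in roles:
        zyg = "DZ"
    return FamilyStructure(
        member_ids=[s.subject_id for s in ordered],
        roles=roles,
        zygosity=zyg,
        kinship=k,
        shared_env=j,
        twin=tm,
    )


def family_covariance(
    structure: FamilyStructure,
    sigma2_a: float,
    sigma2_c: float,
    sigma2_t: float,
    sigma2_e: float,
) -> np.ndarray:
    """Sigma_f = sA2*K + sC2*J + sT2*Tm + sE2*I (symmetric PSD)."""
    for v in (sigma2_a, sigma2_c, sigma2_t, sigma2_e):
        if v < 0:
            raise ValueError("variance components must be nonnegative")
    m = structure.size
    return (
        sigma2_a * structure.kinship
        + sigma2_c * structure.shared_env
        + sigma2_t * structure.twin
        + sigma2_e * np.eye(m)
    )


@dataclass
class _Group:
    """Families sharing a role pattern, stacked for vectorized likelihood."""

    roles: tuple[str, ...]
    kinship: np.ndarray
    shared_env: np.ndarray
    twin: np.ndarray
    x: np.ndarray  # (n_families, m, p)
    subject_rows: np.ndarray  # (n_families, m) indices into the cohort order


@dataclass
class _StatsBundle:
    """Sufficient statistics for the whole cohort, padded to the maximum
    family size and stacked so one likelihood evaluation is a handful of
    batched numpy calls. With members indexed a, b within a role-pattern
    group, G[a,b] = sum_f X_f[a] X_f[b]', H[a,b] = sum_f X_f[a] y_f[b] and
    Q[a,b] = sum_f y_f[a] y_f[b]; every GLS contraction is then a weighted
    sum with weights Sigma^{-1}[a,b], independent of the family count.
    Padding positions carry a fixed unit diagonal (``pad_eye``) and zero
    statistics, so they contribute nothing to determinants or contractions.
    """

    kinship: np.ndarray  # (ngroups, M, M)
    shared_env: np.ndarray
    twin: np.ndarray
    eye_block: np.ndarray  # identity on real members only
    pad_eye: np.ndarray  # identity on padding positions only
    n_families: np.ndarray  # (ngroups,)
    g: np.ndarray  # (ngroups, M, M, p, p)
    h: np.ndarray  # (ngroups, M, M, p)
    q: np.ndarray  # (ngroups, M, M)
    n_total: int


@dataclass
class TwinDesign:
    """Pre-grouped cohort structure reused across per-edge fits."""

    groups: list[_Group]
    covariate_names: list[str]
    n_subjects: int

    @property
    def n_families(self) -> int:
        return sum(g.subject_rows.shape[0] for g in self.groups)

    def gather(self, y: np.ndarray) -> list[np.ndarray]:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_subjects,):
            raise ValueError("phenotype length must match the cohort")
        return [y[g.subject_rows] for g in self.groups]

    def suff_stats(self, y: np.ndarray) -> _StatsBundle:
        ng = len(self.groups)
        mx = max(len(g.roles) for g in self.groups)
        p = self.groups[0].x.shape[2]
        kin = np.zeros((ng, mx, mx))
        sh = np.zeros((ng, mx, mx))
        tw = np.zeros((ng, mx, mx))
        eb = np.zeros((ng, mx, mx))
        pe = np.zeros((ng, mx, mx))
        gg = np.zeros((ng, mx, mx, p, p))
        hh = np.zeros((ng, mx, mx, p))
        qq = np.zeros((ng, mx, mx))
        nf = np.zeros(ng, dtype=int)
        n_total = 0
        for i, (g, yg) in enumerate(zip(self.groups, self.gather(y))):
            m = len(g.roles)
            if not hasattr(g, "_gram"):
                g._gram = np.einsum("fap,fbq->abpq", g.x, g.x)
            kin[i, :m, :m] = g.kinship
            sh[i, :m, :m] = g.shared_env
            tw[i, :m, :m] = g.twin
            eb[i, :m, :m] = np.eye(m)
            pe[i, m:, m:] = np.eye(mx - m)
            gg[i, :m, :m] = g._gram
            hh[i, :m, :m] = np.einsum("fap,fb->abp", g.x, yg)
            qq[i, :m, :m] = yg.T @ yg
            nf[i] = g.x.shape[0]
            n_total += g.x.shape[0] * m
        return _StatsBundle(kin, sh, tw, eb, pe, nf, gg, hh, qq, n_total)


def build_design(cohort: Cohort, covariates=None) -> TwinDesign:
    """Group the cohort's families by role pattern and attach mean-model
    covariates (default: intercept + age + sex; constant covariates are
    dropped with a warning)."""
    row = {sid: i for i, sid in enumerate(cohort.subject_ids)}
    if covariates is None:
        x_all = np.column_stack(
            [
                np.ones(len(cohort)),
                np.array([s.age for s in cohort.subjects], dtype=float),
                np.array([s.sex for s in cohort.subjects], dtype=float),
            ]
        )
        names = ["intercept", "age", "sex"]
    else:
        x_all = np.asarray(covariates, dtype=float)
        names = [f"x{i}" for i in range(x_all.shape[1])]
    keep = [0]
    for j in range(1, x_all.shape[1]):
        if np.ptp(x_all[:, j]) == 0:
            warnings.warn(
                f"covariate {names[j]!r} is constant and was dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            keep.append(j)
    x_all = x_all[:, keep]
    names = [names[j] for j in keep]
    # center non-intercept columns for conditioning
    x_all[:, 1:] -= x_all[:, 1:].mean(axis=0)

    buckets: dict[tuple[str, ...], list[list[int]]] = {}
    for members in cohort.families().values():
        st = family_structure(members)
        idx = [row[sid] for sid in st.member_ids]
        buckets.setdefault(tuple(st.roles), []).append(idx)
    groups = []
    for roles, fam_rows in sorted(buckets.items()):
        k, j, tm = _structure_matrices(list(roles))
        rows_arr = np.array(fam_rows, dtype=int)
        groups.append(
            _Group(
                roles=roles,
                kinship=k,
                shared_env=j,
                twin=tm,
                x=x_all[rows_arr],
                subject_rows=rows_arr,
            )
        )
    return TwinDesign(groups=groups, covariate_names=names, n_subjects=len(cohort))


_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12


def _neg_loglik(variances: np.ndarray, bundle: _StatsBundle) -> tuple[float, np.ndarray]:
    """Gaussian -loglik with the mean coefficients profiled out by GLS,
    evaluated from the precomputed batched sufficient statistics.

    Returns (nll, beta_hat)."""
    va, vc, vt, ve = variances
    p = bundle.g.shape[3]
    sig = (va * bundle.kinship + vc * bundle.shared_env + vt * bundle.twin
           + ve * bundle.eye_block + bundle.pad_eye)
    sign, ld = np.linalg.slogdet(sig)
    if np.any(sign <= 0):
        return _BIG, np.zeros(p)
    si = np.linalg.inv(sig)
    logdet = float(bundle.n_families @ ld)
    a_mat = np.einsum("gab,gabpq->pq", si, bundle.g)
    b_vec = np.einsum("gab,gabp->p", si, bundle.h)
    quad = float(np.einsum("gab,gab->", si, bundle.q))
    try:
        beta = np.linalg.solve(a_mat, b_vec)
    except np.linalg.LinAlgError:
        return _BIG, np.zeros(p)
    rss = quad - 2.0 * b_vec @ beta + beta @ a_mat @ beta
    nll = 0.5 * (logdet + rss + bundle.n_total * _LOG2PI)
    if not np.isfinite(nll):
        return _BIG, beta
    return nll, beta


def acte_loglik(y: np.ndarray, design: TwinDesign, variances) -> float:
    """Log-likelihood at the given (sigma2_A, sigma2_C, sigma2_T, sigma2_E),
    with the mean coefficients profiled out (their ML values)."""
    variances = np.asarray(variances, dtype=float)
    if variances.shape != (4,) or np.any(variances < 0):
        raise ValueError("expected four nonnegative variance components")
    nll, _ = _neg_loglik(variances, design.suff_stats(y))
    return -nll


@dataclass
class ACTEEstimate:
    """Fitted per-edge ACTE decomposition."""

    var_a: float
    var_c: float
    var_t: float
    var_e: float
    a2: float
    c2: float
    t2: float
    e2: float
    beta: dict[str, float]
    loglik: float
    converged: bool
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    significant_a: bool | None = None

    @property
    def variances(self) -> np.ndarray:
        return np.array([self.var_a, self.var_c, self.var_t, self.var_e])

    @property
    def shares(self) -> np.ndarray:
        return np.array([self.a2, self.c2, self.t2, self.e2])


def _nm_minimize(fun, x0, fatol=1e-8, xatol=1e-6, maxiter=2000):
    return optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={"fatol": fatol, "xatol": xatol, "maxiter": maxiter},
    )


def fit_acte(
    y: np.ndarray,
    cohort: Cohort | None = None,
    covariates=None,
    design: TwinDesign | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> ACTEEstimate:
    """Maximum-likelihood ACTE fit for one edge phenotype.

    ``y`` is ordered like ``cohort.subjects``. Components are parameterized
    as squares of unconstrained scalars (nonnegativity by construction) with
    ``n_starts`` seeded multi-starts; optimization failures are flagged via
    ``converged``, not raised. Pass a prebuilt ``design`` when fitting many
    edges of the same cohort.
    """
    if design is None:
        if cohort is None:
            raise ValueError("provide a cohort or a prebuilt design")
        design = build_design(cohort, covariates)
    if design.n_families < 50:
        warnings.warn(
            f"only {design.n_families} families; ACTE estimates will be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    y = np.asarray(y, dtype=float)
    stats_list = design.suff_stats(y)

    def objective(s):
        return _neg_loglik(s * s, stats_list)[0]

    v0 = max(float(np.var(y)), 1e-12)
    rng = np.random.default_rng(seed)
    starts = [np.sqrt(np.full(4, v0 / 4.0))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.sqrt(rng.dirichlet(np.ones(4)) * v0))
    best = None
    any_success = False
    for s0 in starts:
        res = _nm_minimize(objective, s0)
        any_success |= bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    variances = best.x * best.x
    nll, beta = _neg_loglik(variances, stats_list)
    total = float(variances.sum())
    converged = bool(any_success and np.isfinite(nll) and total > 0)
    shares = variances / total if total > 0 else np.full(4, np.nan)
    return ACTEEstimate(
        var_a=float(variances[0]),
        var_c=float(variances[1]),
        var_t=float(variances[2]),
        var_e=float(variances[3]),
        a2=float(shares[0]),
        c2=float(shares[1]),
        t2=float(shares[2]),
        e2=float(shares[3]),
        beta=dict(zip(design.covariate_names, beta.tolist())),
        loglik=float(-nll),
        converged=converged,
    )


def _profile_nll(share: float, comp: int, stats_list, starts):
    """Minimize the nll with one standardized share fixed.

    The fixed component's variance is share/(1-share) times the sum of the
    other three, which enforces the ratio exactly while the others stay free.
    ``starts`` is a list of sqrt-parameter starting points; the best solution
    wins. Returns (nll, optimal sqrt-parameters of the free components)."""
    others = [i for i in range(4) if i != comp]
    ratio = share / (1.0 - share)

    def objective(s3):
        v = np.empty(4)
        free = s3 * s3
        v[others] = free
        v[comp] = ratio * free.sum()
        return _neg_loglik(v, stats_list)[0]

    best = None
    for s0 in starts:
        # deviance comparisons only need ~1e-3 precision; a loose inner
        # tolerance halves the function evaluations
        res = _nm_minimize(objective, s0, fatol=1e-6, xatol=1e-4)
        if best is None or res.fun < best.fun:
            best = res
    return best.fun, best.x


class _ProfileSolver:
    """Profiled deviance of one standardized share with solution
    continuation: every evaluation warm-starts from the nearest previously
    solved share (plus a reallocation start that dumps the fixed component's
    removed variance onto the free components), so large jumps — e.g.
    evaluating at share 0 from a fit with substantial A — cannot stall in a
    local optimum."""

    def __init__(self, fit: ACTEEstimate, y: np.ndarray, design: TwinDesign,
                 comp: int):
        self.comp = comp
        self.stats_list = design.suff_stats(np.asarray(y, dtype=float))
        self.nll_min = -fit.loglik
        others = [i for i in range(4) if i != comp]
        total = fit.variances.sum()
        floor = 1e-8 * max(total, 1e-12)
        warm = np.maximum(fit.variances[others], floor)
        point = float(fit.shares[comp])
        self.solutions: dict[float, np.ndarray] = {point: np.sqrt(warm)}
        # reallocation start: removed variance spread over the free components
        self.spread = np.sqrt(warm + fit.variances[comp] / 3.0)

    def nll(self, share: float) -> float:
        share = min(max(share, 0.0), 1.0 - 1e-9)
        nearest = min(self.solutions, key=lambda v: abs(v - share))
        if abs(nearest - share) > 0.15:
            # step through intermediate shares so the warm start tracks
            for v in np.linspace(nearest, share, 4)[1:-1]:
                self.nll(float(v))
            nearest = min(self.solutions, key=lambda v: abs(v - share))
        starts = [self.solutions[nearest]]
        if share < nearest:
            # shrinking the fixed component forces its variance to
            # reallocate; offer the spread start as an escape route
            starts.append(self.spread)
        val, sol = _profile_nll(share, self.comp, self.stats_list, starts)
        self.solutions[share] = sol
        return val

    def deviance(self, share: float) -> float:
        return max(2.0 * (self.nll(share) - self.nll_min), 0.0)


def profile_ci(
    fit: ACTEEstimate,
    y: np.ndarray,
    design: TwinDesign,
    component: str = "A",
    level: float = 0.95,
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Profile-likelihood CI for a standardized variance share.

    The share is fixed on a grid/bisection, the remaining parameters are
    re-maximized, and the bounds sit where twice the profiled log-likelihood
    drop equals the chi-square(1) critical value. The lower bound is floored
    at 0 and the upper bound capped at 1. Non-converged fits yield (nan, nan).
    """
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}")
    if not fit.converged:
        return (np.nan, np.nan)
    comp = COMPONENTS.index(component)
    crit = stats.chi2.ppf(level, 1)
    point = float(fit.shares[comp])
    solver = _ProfileSolver(fit, y, design, comp)
    cache: dict[float, float] = {}

    def deviance(v: float) -> float:
        if v not in cache:
            cache[v] = solver.deviance(v)
        return cache[v]

    # lower bound
    if point <= tol or deviance(0.0) <= crit:
        lo = 0.0
    else:
        lo = float(optimize.brentq(lambda v: deviance(v) - crit, 0.0, point, xtol=tol))
    # upper bound
    hi_cap = 1.0 - 1e-6
    v_lo, v_hi = point, None
    step = max(0.05, 2 * tol)
    v = point
    while v < hi_cap:
        v = min(v + step, hi_cap)
        if deviance(v) > crit:
            v_hi = v
            break
        v_lo = v
        step *= 1.6
    if v_hi is None:
        hi = 1.0
    else:
        hi = float(optimize.brentq(lambda u: deviance(u) - crit, v_lo, v_hi, xtol=tol))
    return (min(lo, point), max(hi, point))


def significant_a(
    fit: ACTEEstimate, y: np.ndarray, design: TwinDesign, level: float = 0.95
) -> bool | None:
    """Whether the additive-genetic share is significant: the profiled
    deviance at a2 = 0 exceeds the chi-square(1) critical value, i.e. the
    profile CI's lower bound is greater than zero. None if not converged."""
    if not fit.converged:
        return None
    if fit.a2 <= 0:
        return False
    solver = _ProfileSolver(fit, y, design, 0)
    return bool(solver.deviance(0.0) > stats.chi2.ppf(level, 1))


def heritable_fraction(estimates) -> tuple[float, int]:
    """Proportion of converged edges whose A-component is significant
    (profile-CI lower bound > 0). Returns (fraction, n_converged);
    non-converged edges are excluded from the denominator."""
    flags = []
    n_dropped = 0
    for est in estimates:
        if isinstance(est, ACTEEstimate):
            if not est.converged:
                n_dropped += 1
                continue
            if est.significant_a is not None:
                flags.append(bool(est.significant_a))
            elif "A" in est.ci:
                flags.append(est.ci["A"][0] > 0)
            else:
                raise ValueError("estimate lacks both significance flag and A CI")
        elif est is None:
            n_dropped += 1
        else:
            flags.append(bool(est))
    if not flags:
        raise RuntimeError("no converged edges")
    if n_dropped:
        warnings.warn(f"{n_dropped} non-converged edge(s) excluded", RuntimeWarning,
                      stacklevel=2)
    return float(np.mean(flags)), len(flags)
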