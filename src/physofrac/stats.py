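"""Statistical machinery: PERMANOVA, beta-binomial tests, rank tests, FDR.

PERMANOVA follows the distance-based linear-model formulation: the Gower
matrix G = -1/2 J D^2 J is decomposed by projections onto design-matrix
column spaces, sequential (Type I) sums of squares are taken term by term,
and p-values come from free permutation of sample labels with the
(1 + b) / (1 + m) estimator.

The beta-binomial model parameterizes each taxon's read count y out of n by
mean mu and overdispersion phi on logit scales (alpha = mu (1-phi)/phi,
beta = (1-mu)(1-phi)/phi). Differential abundance is a likelihood-ratio test
of group-specific mu against shared mu at shared phi; differential
dispersion tests group-specific phi against shared phi at group-specific mu.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special
from scipy import stats as sps

from .exceptions import InvalidArgument, InvalidDesign

# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InvalidArgument("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Per-term decomposition of a distance matrix."""

    table: pd.DataFrame  # rows: terms + Residual + Total; columns: df, SS, R2, F, p
    n_perm: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _gower(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _dummies(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _projectors(terms: list[np.ndarray], n: int) -> tuple[list[np.ndarray], list[int]]:
    """Cumulative orthonormal bases for intercept + terms 1..k, and term dfs."""
    X = np.ones((n, 1))
    bases, dfs = [], []
    prev_rank = 1
    basis = linalg.orth(X)
    for term in terms:
        X = np.hstack([X, term])
        basis = linalg.orth(X)
        rank = basis.shape[1]
        dfs.append(rank - prev_rank)
        prev_rank = rank
        bases.append(basis)
    return bases, dfs


def _term_stats(G: np.ndarray, bases, dfs):
    """Sequential SS, F and R2 per term given Gower matrix G."""
    n = G.shape[0]
    ss_total = float(np.trace(G))
    ss_terms = []
    prev_expl = 0.0  # the intercept explains nothing after Gower centering
    for basis in bases:
        expl = float(np.einsum("ij,ji->", basis.T @ G, basis))
        ss_terms.append(expl - prev_expl)
        prev_expl = expl
    ss_resid = ss_total - prev_expl
    df_model = sum(dfs)
    df_resid = n - 1 - df_model
    Fs = []
    for ss, df in zip(ss_terms, dfs):
        if df == 0 or df_resid <= 0 or ss_resid <= 0:
            Fs.append(np.nan)
        else:
            Fs.append((ss / df) / (ss_resid / df_resid))
    return ss_terms, ss_resid, ss_total, Fs, df_resid


def permanova_terms(dm, factors: dict[str, np.ndarray], n_perm: int = 999,
                    seed: int | None = None, all_perms: bool = False) -> PermanovaResult:
    """Sequential multi-term PERMANOVA.

    factors: ordered mapping term name -> per-sample labels. Terms are dummy
    coded and entered in order (Type I SS). With all_perms=True every
    permutation is enumerated (n <= 8) and p = #{F_perm >= F_obs} / n!.
    """
    D = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    n = D.shape[0]
    names = list(factors)
    terms = [_dummies(factors[name]) for name in names]
    for t in terms:
        if t.shape[0] != n:
            raise InvalidArgument("factor length does not match distance matrix")
    G = _gower(D)
    bases, dfs = _projectors(terms, n)
    if all(df == 0 for df in dfs):
        raise InvalidDesign("all terms have zero degrees of freedom")
    ss_terms, ss_resid, ss_total, Fs, df_resid = _term_stats(G, bases, dfs)
    if df_resid <= 0:
        raise InvalidDesign("no residual degrees of freedom")

    exceed = np.zeros(len(terms))
    if all_perms:
        from itertools import permutations as iter_perms
        from math import factorial

        if n > 8:
            raise InvalidArgument("exact enumeration supported only for n <= 8")
        total = factorial(n)
        for perm in iter_perms(range(n)):
            Gp = G[np.ix_(perm, perm)]
            _, _, _, Fp, _ = _term_stats(Gp, bases, dfs)
            for i, (fo, fp) in enumerate(zip(Fs, Fp)):
                if not np.isnan(fo) and not np.isnan(fp) and fp >= fo - 1e-12:
                    exceed[i] += 1
        pvals = [exceed[i] / total if not np.isnan(Fs[i]) else np.nan
                 for i in range(len(terms))]
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            _, _, _, Fp, _ = _term_stats(Gp, bases, dfs)
            for i, (fo, fp) in enumerate(zip(Fs, Fp)):
                if not np.isnan(fo) and not np.isnan(fp) and fp >= fo:
                    exceed[i] += 1
        pvals = [(1.0 + exceed[i]) / (1.0 + n_perm) if not np.isnan(Fs[i]) else np.nan
                 for i in range(len(terms))]

    rows = []
    for name, df, ss, F, p in zip(names, dfs, ss_terms, Fs, pvals):
        rows.append({"term": name, "df": df, "SS": ss,
                     "R2": ss / ss_total if ss_total > 0 else np.nan, "F": F, "p": p})
    rows.append({"term": "Residual", "df": df_resid, "SS": ss_resid,
                 "R2": ss_resid / ss_total if ss_total > 0 else np.nan,
                 "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)


def permanova(dm, groups, n_perm: int = 999, seed: int | None = None,
              term: str = "group", all_perms: bool = False) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping factor."""
    labels = np.asarray(groups)
    if len(pd.unique(labels)) < 2:
        raise InvalidDesign("PERMANOVA needs at least two groups")
    return permanova_terms(dm, {term: labels}, n_perm=n_perm, seed=seed,
                           all_perms=all_perms)


def nested_permanova(dm, outer, inner, n_perm: int = 999, seed: int | None = None,
                     outer_name: str = "outer", inner_name: str = "inner") -> PermanovaResult:
    """Sequential model: outer factor, then inner nested within outer.

    The nested term is the outer x inner combination factor entered after the
    outer main effect, mirroring the `inner %in% outer` formula convention.
    """
    outer = np.asarray(outer)
    inner = np.asarray(inner)
    if outer.shape != inner.shape:
        raise InvalidDesign("outer and inner factors must have equal length")
    if len(pd.unique(outer)) < 2:
        raise InvalidDesign("outer factor needs at least two levels")
    combo = np.array([f"{o}\x1f{i}" for o, i in zip(outer, inner)])
    return permanova_terms(
        dm,
        {outer_name: outer, f"{inner_name} %in% {outer_name}": combo},
        n_perm=n_perm, seed=seed,
    )


def pairwise_permanova(dm, groups, n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """One-way PERMANOVA for every pair of group levels, BH-adjusted."""
    from itertools import combinations

    from skbio import DistanceMatrix

    labels = pd.Series(np.asarray(groups), index=list(dm.ids))
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise InvalidDesign("need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(levels, 2):
        ids = list(labels.index[labels.isin([a, b])])
        sub = dm.filter(ids)
        res = permanova(sub, labels.loc[ids].to_numpy(), n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        row = res.table.loc["group"]
        rows.append({"group_a": a, "group_b": b, "df": row["df"],
                     "R2": row["R2"], "F": row["F"], "p": row["p"]})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# beta-binomial differential abundance / dispersion
# ---------------------------------------------------------------------------

def _ab(mu: float, phi: float) -> tuple[float, float]:
    a = mu * (1.0 - phi) / phi
    b = (1.0 - mu) * (1.0 - phi) / phi
    return a, b


def betabinom_loglik(y, n, mu, phi) -> float:
    """Beta-binomial log-likelihood, summed over observations.

    mu and phi may be scalars or per-observation arrays in (0, 1).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise InvalidArgument("require 0 <= y <= n")
    if np.any(mu <= 0) or np.any(mu >= 1) or np.any(phi <= 0) or np.any(phi >= 1):
        raise InvalidArgument("mu and phi must lie in (0, 1)")
    a = mu * (1.0 - phi) / phi
    b = (1.0 - mu) * (1.0 - phi) / phi
    ll = (special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
          + special.betaln(y + a, n - y + b) - special.betaln(a, b))
    return float(ll.sum())


@dataclass
class BetaBinomResult:
    """Per-taxon beta-binomial test result."""

    taxon: str
    mu: dict  # group (or "shared") -> fitted mu
    phi: dict  # group (or "shared") -> fitted phi
    lrt_abundance: float
    p_abundance: float
    lrt_dispersion: float
    p_dispersion: float
    converged: bool = True
    q_abundance: float = field(default=np.nan)
    q_dispersion: float = field(default=np.nan)


def _nll_factory(y, n, group_idx, n_groups, group_mu: bool, group_phi: bool):
    """Negative log-likelihood over unconstrained logit parameters."""
    def nll(params):
        k = n_groups if group_mu else 1
        mu = special.expit(params[:k])
        phi = special.expit(params[k:])
        mu_obs = mu[group_idx] if group_mu else mu[0]
        phi_obs = phi[group_idx] if group_phi else phi[0]
        mu_obs = np.clip(mu_obs, 1e-10, 1 - 1e-10)
        phi_obs = np.clip(phi_obs, 1e-10, 1 - 1e-10)
        a = mu_obs * (1.0 - phi_obs) / phi_obs
        b = (1.0 - mu_obs) * (1.0 - phi_obs) / phi_obs
        ll = special.betaln(y + a, n - y + b) - special.betaln(a, b)
        return -float(ll.sum())
    return nll


def _fit(y, n, group_idx, n_groups, group_mu, group_phi, starts):
    nll = _nll_factory(y, n, group_idx, n_groups, group_mu, group_phi)
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best


def _mom_start(y, n):
    p = y / np.maximum(n, 1)
    mu0 = float(np.clip(p.mean(), 1e-4, 1 - 1e-4))
    nbar = float(n.mean())
    denom = mu0 * (1 - mu0)
    phi0 = 0.05
    if denom > 0 and nbar > 1:
        excess = p.var(ddof=1) - denom / nbar
        phi0 = excess / denom * nbar / (nbar - 1) if excess > 0 else 0.01
    phi0 = float(np.clip(phi0, 1e-4, 0.9))
    return mu0, phi0


def fit_betabinom_test(counts, totals, groups, taxon: str = "") -> BetaBinomResult:
    """LRTs for differential abundance (mu) and dispersion (phi) of one taxon.

    counts: per-sample reads of the taxon; totals: per-sample library sizes;
    groups: per-sample labels (>= 2 samples per group required).
    """
    y = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    labels = np.asarray(groups)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise InvalidDesign("need at least two groups")
    for lev in levels:
        if (labels == lev).sum() < 2:
            raise InvalidDesign(f"group {lev!r} has fewer than 2 samples")
    if y.sum() == 0 or np.all(y == n):
        return BetaBinomResult(taxon, {}, {}, np.nan, np.nan, np.nan, np.nan,
                               converged=False)
    group_idx = np.array([levels.index(l) for l in labels])
    n_groups = len(levels)

    mu0, phi0 = _mom_start(y, n)
    l_mu0, l_phi0 = special.logit(mu0), special.logit(phi0)

    # null: shared mu, shared phi
    m0 = _fit(y, n, group_idx, n_groups, False, False,
              [np.array([l_mu0, l_phi0]), np.array([l_mu0, special.logit(0.01)])])
    # alt abundance: group mu, shared phi (warm start from null)
    mu_g0 = np.array([special.logit(np.clip((y[group_idx == g] / n[group_idx == g]).mean(),
                                            1e-4, 1 - 1e-4)) for g in range(n_groups)])
    m1 = _fit(y, n, group_idx, n_groups, True, False,
              [np.concatenate([np.full(n_groups, m0.x[0]), m0.x[1:]]),
               np.concatenate([mu_g0, m0.x[1:]])])
    # alt dispersion: group mu, group phi (warm start from m1)
    m2 = _fit(y, n, group_idx, n_groups, True, True,
              [np.concatenate([m1.x[:n_groups], np.full(n_groups, m1.x[n_groups])]),
               np.concatenate([mu_g0, np.full(n_groups, l_phi0)])])

    lrt_ab = max(0.0, 2.0 * (m0.fun - m1.fun))
    lrt_disp = max(0.0, 2.0 * (m1.fun - m2.fun))
    df = n_groups - 1
    p_ab = float(sps.chi2.sf(lrt_ab, df))
    p_disp = float(sps.chi2.sf(lrt_disp, df))
    mu_hat = {lev: float(special.expit(m1.x[g])) for g, lev in enumerate(levels)}
    mu_hat["shared"] = float(special.expit(m0.x[0]))
    phi_hat = {lev: float(special.expit(m2.x[n_groups + g])) for g, lev in enumerate(levels)}
    phi_hat["shared"] = float(special.expit(m1.x[n_groups]))
    converged = bool(m0.success and m1.success and m2.success)
    return BetaBinomResult(taxon, mu_hat, phi_hat, lrt_ab, p_ab, lrt_disp, p_disp,
                           converged=converged)


def betabinom_test_table(table_counts: pd.DataFrame, groups, min_total_reads: int = 1) -> pd.DataFrame:
    """fit_betabinom_test for every ASV column, with BH q-values across taxa."""
    totals = table_counts.sum(axis=1).to_numpy()
    labels = np.asarray(groups)
    rows = []
    for taxon in table_counts.columns:
        y = table_counts[taxon].to_numpy()
        if y.sum() < min_total_reads:
            rows.append({"taxon": taxon, "p_abundance": np.nan, "p_dispersion": np.nan,
                         "converged": False})
            continue
        res = fit_betabinom_test(y, totals, labels, taxon=taxon)
        row = {"taxon": taxon, "p_abundance": res.p_abundance,
               "p_dispersion": res.p_dispersion, "converged": res.converged}
        for g, m in res.mu.items():
            row[f"mu_{g}"] = m
        for g, f in res.phi.items():
            row[f"phi_{g}"] = f
        rows.append(row)
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_abundance"] = bh_adjust(out["p_abundance"].to_numpy())
    out["q_dispersion"] = bh_adjust(out["p_dispersion"].to_numpy())
    return out.sort_values("q_abundance")


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p."""
    if len(groups) < 2:
        raise InvalidDesign("need at least two groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(pooled).size < 2:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def dunn_posthoc(groups: list, labels: list | None = None) -> pd.DataFrame:
    """Dunn's z post hoc on pooled ranks with tie correction; BH-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    """
    from itertools import combinations

    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start:start + s].mean())
        start += s
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgument("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidArgument("constant vector has undefined correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def anova_vs_control(values, group_labels, control: str = "Control") -> pd.DataFrame:
    """One-way ANOVA across all groups plus Welch t-tests of each treatment
    against the control, BH-adjusted across treatments."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    levels = list(pd.unique(labels))
    if control not in levels:
        raise InvalidDesign(f"control group {control!r} missing")
    groups = {lev: values[labels == lev] for lev in levels}
    for lev, v in groups.items():
        if v.size < 2:
            raise InvalidDesign(f"group {lev!r} has fewer than 2 replicates")
    if all(np.ptp(v) == 0 for v in groups.values()) and \
            np.ptp([v.mean() for v in groups.values()]) == 0:
        anova_p = 1.0  # no variance anywhere: nothing to test
        anova_f = 0.0
    else:
        anova_f, anova_p = sps.f_oneway(*groups.values())
        anova_f, anova_p = float(anova_f), float(anova_p)
    rows = []
    for lev in levels:
        if lev == control:
            continue
        a, b = groups[lev], groups[control]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            t, p = float(t), float(p)
        rows.append({"group": lev, "mean": a.mean(), "control_mean": b.mean(),
                     "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["anova_F"] = anova_f
    out.attrs["anova_p"] = anova_p
    return out
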