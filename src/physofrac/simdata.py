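"""Synthetic FACS-sorted gut-community generator.

The generator emulates a cohort of individuals whose fecal communities are
stained, gated into physiological fractions (HNA/LNA by nucleic-acid
content, BONCAT+/- by translational activity, PI+ by membrane damage),
sorted on a cytometer with imperfect gate purity, and sequenced as 16S
amplicon libraries with sheath-fluid contamination and negative controls.

Latent structure:
  * per-individual fraction proportions pi_if (percent of cells in each
    gate) follow a Gaussian copula with truncated-normal marginals whose
    realized moments equal the configured means/SDs/correlations;
  * each taxon t has a membership propensity theta_tf (probability a cell of
    taxon t falls in fraction f), shaped by phylum and by core/unique status;
  * a per-individual logit offset delta_if calibrates aggregate membership
    sum_t a_t * logistic(logit(theta_tf) + delta_if) to pi_if / 100 exactly;
  * sorting draws events from the in-gate taxon distribution with
    probability 1 - gate_error, otherwise from the out-of-gate complement;
  * sequencing is multinomial at fixed depth, plus sheath-fluid contaminant
    reads in sorted samples and sheath-only negative controls.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from skbio import TreeNode

from .exceptions import (
    DegenerateFraction,
    InvalidArgument,
    UnreachableTarget,
)
from .io_formats import CountTable, CytometryCounts

#: Fractions with their own latent proportion (LNA and BONCAT- are complements).
BASE_FRACTIONS = ("HNA", "BONCATpos", "PIpos")

_GATE_COMPLEMENTS = {"LNA": "HNA", "BONCATneg": "BONCATpos"}

DEFAULT_TREATMENT_EFFECTS = {
    # individual -> treatment -> fraction -> (mean %, replicate SD %)
    1: {
        "Control": {"HNA": (65.0, 4.0), "BONCATpos": (28.0, 17.0), "PIpos": (10.0, 0.96)},
        "Glucose": {"HNA": (56.0, 3.2), "BONCATpos": (60.0, 7.9), "PIpos": (6.5, 0.94)},
        "Digoxin": {"HNA": (89.0, 1.5), "BONCATpos": (28.0, 17.0), "PIpos": (10.0, 0.96)},
        "Nizatidine": {"HNA": (85.0, 5.5), "BONCATpos": (28.0, 17.0), "PIpos": (10.0, 0.96)},
    },
    2: {
        "Control": {"HNA": (51.73, 4.0), "BONCATpos": (27.0, 7.5), "PIpos": (15.73, 4.0)},
        "Glucose": {"HNA": (51.73, 4.0), "BONCATpos": (67.0, 3.5), "PIpos": (15.73, 4.0)},
        "Digoxin": {"HNA": (51.73, 4.0), "BONCATpos": (27.0, 7.5), "PIpos": (15.73, 4.0)},
        "Nizatidine": {"HNA": (51.73, 4.0), "BONCATpos": (27.0, 7.5), "PIpos": (15.73, 4.0)},
    },
}


def _default_corr() -> np.ndarray:
    # order (HNA, BONCATpos, PIpos); the unreported r(BONCAT+, PI+) is
    # completed as the conditional-independence product r(H,P) * r(H,B).
    r_hb, r_hp = -0.62, 0.74
    r_bp = r_hb * r_hp
    return np.array([[1.0, r_hb, r_hp],
                     [r_hb, 1.0, r_bp],
                     [r_hp, r_bp, 1.0]])


@dataclass
class SimConfig:
    """All generator parameters. Defaults encode the study conditions."""

    n_individuals: int = 10
    n_taxa: int = 838
    core_count: int = 12
    unique_count: int = 477
    relaxed_core_count: int = 32  # present in >= ceil(0.8 n) individuals (core included)
    phylum_labels: tuple = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
    phylum_probs: tuple = (0.61, 0.30, 0.05, 0.04)
    abundance_lognormal_sigma: float = 1.0  # individual-level log-abundance SD
    taxon_lognormal_sigma: float = 1.25  # taxon-level SD shared across individuals
    core_abundance_bonus: float = 2.5  # log-scale mean shift for core/relaxed-core taxa
    core_stability: float = 0.25  # multiplier on individual-level SD for core taxa
    fraction_means: dict = field(default_factory=lambda: {
        "HNA": 51.73, "BONCATpos": 49.01, "PIpos": 15.73})
    fraction_sds: dict = field(default_factory=lambda: {
        "HNA": 17.59, "BONCATpos": 18.54, "PIpos": 14.58})
    fraction_corr: np.ndarray = field(default_factory=_default_corr)
    propensity_base: dict = field(default_factory=lambda: {
        "HNA": 0.25, "BONCATpos": 0.5, "PIpos": 0.15})
    propensity_logit_sd: float = 0.6
    calibration: str = "scale"  # "scale" (probability scaling) or "logit" (additive shift)
    phylum_logit_offsets: dict = field(default_factory=lambda: {
        "HNA": {"Firmicutes": 2.0, "Actinobacteria": -2.0},
        "PIpos": {"Firmicutes": 1.2, "Actinobacteria": -1.0}})
    core_logit_offsets: dict = field(default_factory=lambda: {"HNA": 2.5})
    unique_logit_offsets: dict = field(default_factory=lambda: {"HNA": -2.5})
    sort_events: int = 180_000
    gate_error: dict = field(default_factory=lambda: {
        "HNA": 0.05, "LNA": 0.05, "BONCATpos": 0.20, "BONCATneg": 0.057, "PIpos": 0.05})
    seq_depth: int = 30_000
    sheath_read_range: tuple = (341, 2333)
    n_contaminant_asvs: int = 2
    cyto_total_events: int = 100_000
    treatment_effects: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_TREATMENT_EFFECTS))
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.fraction_corr = np.asarray(self.fraction_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_taxa < 2 or self.n_individuals < 1:
            raise InvalidArgument("n_taxa >= 2 and n_individuals >= 1 required")
        if self.core_count + self.unique_count > self.n_taxa:
            raise InvalidArgument("core_count + unique_count exceeds n_taxa")
        if not (self.core_count <= self.relaxed_core_count):
            raise InvalidArgument("relaxed_core_count must include core_count")
        C = self.fraction_corr
        if C.shape != (3, 3) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise InvalidArgument("fraction_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise InvalidArgument("fraction_corr is not positive semi-definite")
        for d in (self.gate_error, self.propensity_base):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise InvalidArgument(f"probability {k}={v} outside [0, 1]")
        lo, hi = self.sheath_read_range
        if lo > hi or lo < 0:
            raise InvalidArgument("invalid sheath_read_range")
        for name in ("sort_events", "seq_depth", "n_replicates", "cyto_total_events"):
            if getattr(self, name) <= 0:
                raise InvalidArgument(f"{name} must be positive")
        if self.calibration not in ("scale", "logit"):
            raise InvalidArgument("calibration must be 'scale' or 'logit'")
        if len(self.phylum_probs) != len(self.phylum_labels):
            raise InvalidArgument("phylum_probs must match phylum_labels")

    @property
    def relaxed_threshold(self) -> int:
        return int(np.ceil(0.8 * self.n_individuals))

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """Reduced problem sizes for fast exercises; effect settings unchanged."""
        base = dict(n_taxa=80, core_count=6, unique_count=30, relaxed_core_count=10,
                    sort_events=20_000, seq_depth=3_000, cyto_total_events=20_000,
                    sheath_read_range=(341, 2333))
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_corr"] = self.fraction_corr.tolist()
        return d


# ---------------------------------------------------------------------------
# fraction-proportion copula
# ---------------------------------------------------------------------------

_LO, _HI = 0.0, 100.0
_copula_cache: dict = {}


def _truncnorm_latent(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) so the [0, 100]-truncated normal has the given
    mean and sd."""
    def resid(x):
        mu, lsig = x
        sig = np.exp(lsig)
        a, b = (_LO - mu) / sig, (_HI - mu) / sig
        tm, tv = sps.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(tm) - mean, float(np.sqrt(tv)) - sd]

    sol = optimize.root(resid, [mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise InvalidArgument(f"no truncated-normal margin with mean={mean}, sd={sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


class _CopulaSampler:
    """Gaussian copula with moment-matched truncated-normal marginals.

    Latent marginal parameters are solved so the truncated moments equal the
    configured ones; latent pairwise correlations are solved (monotone
    root-finding with Gauss-Hermite quadrature) so the realized Pearson
    correlations equal the configured ones.
    """

    _gh_x, _gh_w = np.polynomial.hermite_e.hermegauss(64)

    def __init__(self, means: np.ndarray, sds: np.ndarray, corr: np.ndarray):
        self.means, self.sds = means, sds
        self.active = sds > 0
        self.latent = [
            _truncnorm_latent(m, s) if s > 0 else (m, 0.0)
            for m, s in zip(means, sds)
        ]
        self._gh_w = self._gh_w / self._gh_w.sum()
        k = len(means)
        R = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                if self.active[i] and self.active[j] and corr[i, j] != 0.0:
                    R[i, j] = R[j, i] = self._latent_rho(i, j, corr[i, j])
        w, V = np.linalg.eigh(R)
        if w.min() < 1e-10:
            w = np.clip(w, 1e-10, None)
            R = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        self.latent_corr = R

    def _margin_ppf(self, i: int, u: np.ndarray) -> np.ndarray:
        mu, sig = self.latent[i]
        a, b = (_LO - mu) / sig, (_HI - mu) / sig
        return sps.truncnorm.ppf(u, a, b, loc=mu, scale=sig)

    def _pair_corr(self, i: int, j: int, rho: float) -> float:
        x, w = self._gh_x, self._gh_w
        vi = self._margin_ppf(i, sps.norm.cdf(x))
        mi = float(w @ vi)
        si = float(np.sqrt(w @ (vi - mi) ** 2))
        z2 = rho * x[:, None] + np.sqrt(max(0.0, 1 - rho ** 2)) * x[None, :]
        vj = self._margin_ppf(j, sps.norm.cdf(z2))
        e_xy = float(w @ (vj @ w * vi))
        vj_diag = self._margin_ppf(j, sps.norm.cdf(x))
        mj = float(w @ vj_diag)
        sj = float(np.sqrt(w @ (vj_diag - mj) ** 2))
        return (e_xy - mi * mj) / (si * sj)

    def _latent_rho(self, i: int, j: int, target: float) -> float:
        f = lambda r: self._pair_corr(i, j, r) - target
        lo, hi = -0.9999, 0.9999
        if f(lo) > 0 or f(hi) < 0:
            raise UnreachableTarget(
                f"target correlation {target} unreachable for these marginals")
        return float(optimize.brentq(f, lo, hi, xtol=1e-7))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        k = len(self.means)
        out = np.empty((n, k))
        L = np.linalg.cholesky(self.latent_corr + 1e-12 * np.eye(k))
        Z = rng.standard_normal((n, k)) @ L.T
        U = sps.norm.cdf(Z)
        for i in range(k):
            if self.active[i]:
                out[:, i] = self._margin_ppf(i, U[:, i])
            else:
                out[:, i] = self.means[i]
        return out


def _get_sampler(config: SimConfig) -> _CopulaSampler:
    means = np.array([config.fraction_means[f] for f in BASE_FRACTIONS])
    sds = np.array([config.fraction_sds[f] for f in BASE_FRACTIONS])
    key = (tuple(means), tuple(sds), config.fraction_corr.tobytes())
    if key not in _copula_cache:
        _copula_cache[key] = _CopulaSampler(means, sds, config.fraction_corr)
    return _copula_cache[key]


def draw_fraction_proportions(config: SimConfig, seed: int | None = None,
                              n: int | None = None) -> pd.DataFrame:
    """Per-individual fraction proportions (percent): HNA, LNA, BONCAT+, PI+.

    LNA is the SYBR complement 100 - HNA.
    """
    if np.linalg.eigvalsh(config.fraction_corr).min() < -1e-8:
        raise InvalidArgument("fraction_corr is not positive semi-definite")
    n = config.n_individuals if n is None else n
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sampler = _get_sampler(config)
    X = sampler.draw(n, rng)
    out = pd.DataFrame(X, columns=list(BASE_FRACTIONS),
                       index=[f"I{i + 1:02d}" for i in range(n)])
    out.insert(1, "LNA", 100.0 - out["HNA"])
    out.index.name = "individual"
    return out


# ---------------------------------------------------------------------------
# phylogeny and taxonomy
# ---------------------------------------------------------------------------

def _pure_birth(leaf_names: list[str], rng: np.random.Generator,
                mean_length: float = 0.1) -> TreeNode:
    """Yule topology over the given leaves with exponential branch lengths."""
    root = TreeNode()
    leaves = [root]
    while len(leaves) < len(leaf_names):
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        children = [TreeNode(), TreeNode()]
        node.extend(children)
        leaves.extend(children)
    for name, leaf in zip(leaf_names, leaves):
        leaf.name = name
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(mean_length)) + 1e-6
    return root


def simulate_tree(n_taxa: int, seed: int | None = None,
                  phylum_labels=None, phylum_probs=None,
                  stem_length: float = 0.75) -> TreeNode:
    """Rooted binary pure-birth tree over ASV0001..ASVnnnn.

    Phyla are monophyletic: one subtree per phylum, ladder-joined at the
    root; each phylum's ancestral node is named after the phylum. Phylum stem
    branches are long relative to within-phylum branches, as in 16S
    phylogenies where phyla are deeply separated.
    """
    if n_taxa < 2:
        raise InvalidArgument("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    names = [f"ASV{i + 1:04d}" for i in range(n_taxa)]
    if phylum_labels is None:
        phylum_labels = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
        phylum_probs = (0.61, 0.30, 0.05, 0.04)
    if phylum_probs is None:
        phylum_probs = tuple(1.0 / len(phylum_labels) for _ in phylum_labels)
    sizes = rng.multinomial(n_taxa, np.asarray(phylum_probs, dtype=float))
    # drop empty phyla when n_taxa is small; steal one leaf if all landed in one bin
    while (sizes > 0).sum() < min(len(phylum_labels), n_taxa) and n_taxa >= len(phylum_labels):
        donor = int(np.argmax(sizes))
        recipient = int(np.argmin(sizes))
        if sizes[recipient] > 0:
            break
        sizes[donor] -= 1
        sizes[recipient] += 1
    subtrees, start = [], 0
    for label, size in zip(phylum_labels, sizes):
        if size == 0:
            continue
        block = names[start:start + size]
        start += size
        if size == 1:
            sub = TreeNode(name=block[0])
        else:
            sub = _pure_birth(block, rng)
        sub.length = stem_length + float(rng.exponential(0.1))
        if not sub.is_tip():
            sub.name = label
        subtrees.append(sub)
    tree = subtrees[0]
    for sub in subtrees[1:]:
        join = TreeNode()
        join.extend([tree, sub])
        join.length = float(rng.exponential(0.1)) + 1e-6
        tree = join
    tree.length = None
    return tree


def taxonomy_from_tree(tree: TreeNode, phylum_labels=None) -> pd.DataFrame:
    """Taxonomy table derived from the named phylum clades of a simulated tree."""
    if phylum_labels is None:
        phylum_labels = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
    rows = {}
    label_set = set(phylum_labels)
    for node in tree.traverse(include_self=True):
        if node.name in label_set:
            for k, tip in enumerate(node.tips()):
                rows[tip.name] = {"domain": "Bacteria", "phylum": node.name,
                                  "genus": f"g__{node.name[:4]}_{k // 10 + 1}"}
    for tip in tree.tips():  # single-leaf phyla or unlabeled leftovers
        if tip.name not in rows:
            rows[tip.name] = {"domain": "Bacteria", "phylum": phylum_labels[-1],
                              "genus": f"g__{phylum_labels[-1][:4]}_1"}
    tax = pd.DataFrame.from_dict(rows, orient="index")
    tax.index.name = "asv"
    return tax.sort_index()


# ---------------------------------------------------------------------------
# abundances with core/unique/shared prevalence structure
# ---------------------------------------------------------------------------

def simulate_abundances(config: SimConfig, seed: int | None = None,
                        taxa: list[str] | None = None) -> pd.DataFrame:
    """Individuals x taxa relative abundances realizing the configured
    core / relaxed-core / shared / unique prevalence structure exactly."""
    n_ind, n_taxa = config.n_individuals, config.n_taxa
    relaxed_extra = config.relaxed_core_count - config.core_count
    n_shared = n_taxa - config.core_count - config.unique_count - relaxed_extra
    if n_shared < 0:
        raise InvalidArgument("prevalence structure infeasible for n_taxa")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if taxa is None:
        taxa = [f"ASV{i + 1:04d}" for i in range(n_taxa)]
    individuals = [f"I{i + 1:02d}" for i in range(n_ind)]
    order = rng.permutation(n_taxa)
    core_idx = order[:config.core_count]
    relax_idx = order[config.core_count:config.core_count + relaxed_extra]
    uniq_idx = order[config.core_count + relaxed_extra:
                     config.core_count + relaxed_extra + config.unique_count]
    shared_idx = order[config.core_count + relaxed_extra + config.unique_count:]

    presence = np.zeros((n_ind, n_taxa), dtype=bool)
    presence[:, core_idx] = True
    thr = config.relaxed_threshold
    for t in relax_idx:
        k = int(rng.integers(thr, n_ind)) if n_ind > thr else thr
        presence[rng.choice(n_ind, size=k, replace=False), t] = True
    # unique taxa round-robin so every individual owns some
    owners = rng.permutation(np.arange(len(uniq_idx)) % n_ind)
    for t, owner in zip(uniq_idx, owners):
        presence[owner, t] = True
    hi_shared = max(2, thr - 1)
    for t in shared_idx:
        k = int(rng.integers(2, hi_shared + 1)) if n_ind > 2 else 2
        k = min(k, n_ind)
        presence[rng.choice(n_ind, size=k, replace=False), t] = True

    # log-abundance = taxon effect (shared across individuals; core taxa get a
    # mean bonus, the occupancy-abundance relationship) + individual deviation
    taxon_mean = rng.normal(0.0, config.taxon_lognormal_sigma, size=n_taxa)
    taxon_mean[core_idx] += config.core_abundance_bonus
    taxon_mean[relax_idx] += config.core_abundance_bonus
    ind_sd = np.full(n_taxa, config.abundance_lognormal_sigma)
    ind_sd[core_idx] *= config.core_stability  # core taxa are stable across people
    ind_sd[relax_idx] *= config.core_stability
    log_values = taxon_mean[None, :] + ind_sd[None, :] * rng.normal(
        0.0, 1.0, size=presence.shape)
    values = np.where(presence, np.exp(log_values), 0.0)
    values /= values.sum(axis=1, keepdims=True)
    return pd.DataFrame(values, index=individuals, columns=taxa)


def presence_fixture_table(config: SimConfig, seed: int | None = None) -> CountTable:
    """Whole-sample count table whose presence pattern equals the generated
    prevalence structure exactly (every nonzero abundance gets >= 1 read).

    Multinomial sequencing can drop very rare taxa; this fixture sidesteps
    that sampling noise for exact partition arithmetic.
    """
    abundance = simulate_abundances(config, seed=seed)
    counts = np.round(abundance.to_numpy() * config.seq_depth).astype(np.int64)
    counts[(abundance.to_numpy() > 0) & (counts == 0)] = 1
    ids = [f"{ind}_Whole" for ind in abundance.index]
    meta = pd.DataFrame({"individual": list(abundance.index), "fraction": "Whole",
                         "treatment": "NA", "replicate": 1}, index=ids)
    return CountTable(pd.DataFrame(counts, index=ids, columns=abundance.columns), meta)


# ---------------------------------------------------------------------------
# propensities and calibration
# ---------------------------------------------------------------------------

def build_propensities(config: SimConfig, taxonomy: pd.DataFrame,
                       abundance: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Per-taxon membership probability theta_tf for each base fraction.

    logit(theta_tf) = logit(base_f) + phylum offset + core/unique offset +
    taxon-level noise.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    taxa = list(abundance.columns)
    prevalence = (abundance > 0).sum(axis=0)
    is_core = prevalence >= config.n_individuals
    is_unique = prevalence == 1
    out = {}
    for frac in BASE_FRACTIONS:
        base = special.logit(config.propensity_base[frac])
        noise = rng.normal(0.0, config.propensity_logit_sd, size=len(taxa))
        logits = np.full(len(taxa), base) + noise
        ph_off = config.phylum_logit_offsets.get(frac, {})
        if ph_off:
            phyla = taxonomy.reindex(taxa)["phylum"]
            logits += phyla.map(lambda p: ph_off.get(p, 0.0)).to_numpy(dtype=float)
        logits += np.where(is_core.to_numpy(), config.core_logit_offsets.get(frac, 0.0), 0.0)
        logits += np.where(is_unique.to_numpy(), config.unique_logit_offsets.get(frac, 0.0), 0.0)
        out[frac] = np.clip(special.expit(logits), 1e-6, 1 - 1e-6)
    return pd.DataFrame(out, index=taxa)


def calibrate_propensities(abundance_row, base_propensity, target_pi: float) -> float:
    """Logit shift delta with sum_t a_t * logistic(logit(theta_t) + delta)
    = target_pi / 100, found by monotone root-finding (residual <= 1e-8)."""
    a = np.asarray(abundance_row, dtype=float)
    theta = np.asarray(base_propensity, dtype=float)
    if not np.isclose(a.sum(), 1.0, atol=1e-6):
        raise InvalidArgument("abundances must sum to 1")
    if np.any((theta <= 0) | (theta >= 1)):
        raise InvalidArgument("propensities must lie in (0, 1)")
    if not 0.0 < target_pi < 100.0:
        raise UnreachableTarget(f"target {target_pi}% outside (0, 100)")
    target = target_pi / 100.0
    logit_theta = special.logit(theta)

    def f(delta):
        return float(a @ special.expit(logit_theta + delta)) - target

    lo, hi = -60.0, 60.0
    if f(lo) > 0 or f(hi) < 0:
        raise UnreachableTarget(f"target {target_pi}% unreachable")
    delta = float(optimize.brentq(f, lo, hi, xtol=1e-13, maxiter=200))
    if abs(f(delta)) > 1e-8:  # pragma: no cover - brentq converges well before this
        raise UnreachableTarget("calibration residual above 1e-8")
    return delta


def calibrate_activity_scale(abundance_row, base_propensity, target_pi: float) -> float:
    """Scale factor c with sum_t a_t * min(1, c * theta_t) = target_pi / 100.

    Unlike a logit shift, probability scaling preserves the relative taxon
    composition of the in-gate pool for every unclipped taxon, so an
    individual's gate proportion does not reshape the gate's community.
    """
    a = np.asarray(abundance_row, dtype=float)
    theta = np.asarray(base_propensity, dtype=float)
    if not np.isclose(a.sum(), 1.0, atol=1e-6):
        raise InvalidArgument("abundances must sum to 1")
    if np.any((theta <= 0) | (theta >= 1)):
        raise InvalidArgument("propensities must lie in (0, 1)")
    if not 0.0 < target_pi < 100.0:
        raise UnreachableTarget(f"target {target_pi}% outside (0, 100)")
    target = target_pi / 100.0
    present = a > 0
    if not present.any():
        raise InvalidArgument("empty abundance vector")
    hi = 1.0 / theta[present].min()

    def g(c):
        return float(a @ np.minimum(1.0, c * theta)) - target

    if g(hi) < 0:  # target above reachable mass (= sum of present abundances)
        raise UnreachableTarget(f"target {target_pi}% unreachable")
    c = float(optimize.brentq(g, 0.0, hi, xtol=1e-13, maxiter=200))
    if abs(g(c)) > 1e-8:  # pragma: no cover
        raise UnreachableTarget("calibration residual above 1e-8")
    return c


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Latent ground truth of a simulated cohort."""

    config: SimConfig
    tree: TreeNode
    taxonomy: pd.DataFrame
    abundance: pd.DataFrame  # individuals x taxa, rows sum to 1
    proportions: pd.DataFrame  # individuals x (HNA, LNA, BONCATpos, PIpos), percent
    propensities: pd.DataFrame  # taxa x BASE_FRACTIONS
    offsets: pd.DataFrame  # individuals x BASE_FRACTIONS (scale factors or logit shifts)

    @property
    def individuals(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)

    def calibrated_theta(self, individual: str, gate: str) -> np.ndarray:
        """Membership probability per taxon for a sorted gate, after the
        individual's calibration; complements for LNA / BONCAT-."""
        base = _GATE_COMPLEMENTS.get(gate, gate)
        theta = self.propensities[base].to_numpy()
        off = self.offsets.at[individual, base]
        if self.config.calibration == "scale":
            cal = np.minimum(1.0, off * theta)
        else:
            cal = special.expit(special.logit(theta) + off)
        return 1.0 - cal if gate in _GATE_COMPLEMENTS else cal

    @classmethod
    def make(cls, config: SimConfig) -> "Cohort":
        ss = np.random.SeedSequence(config.seed)
        s_tree, s_abund, s_props, s_theta = (int(c.generate_state(1)[0] % (2 ** 31))
                                             for c in ss.spawn(4))
        tree = simulate_tree(config.n_taxa, seed=s_tree,
                             phylum_labels=config.phylum_labels,
                             phylum_probs=config.phylum_probs)
        taxonomy = taxonomy_from_tree(tree, config.phylum_labels)
        abundance = simulate_abundances(config, seed=s_abund,
                                        taxa=[t.name for t in tree.tips()])
        abundance = abundance[sorted(abundance.columns)]
        proportions = draw_fraction_proportions(config, seed=s_props)
        propensities = build_propensities(config, taxonomy, abundance, seed=s_theta)
        calibrate = (calibrate_activity_scale if config.calibration == "scale"
                     else calibrate_propensities)
        offsets = pd.DataFrame(index=abundance.index, columns=list(BASE_FRACTIONS), dtype=float)
        for ind in abundance.index:
            for frac in BASE_FRACTIONS:
                offsets.at[ind, frac] = calibrate(
                    abundance.loc[ind].to_numpy(),
                    propensities[frac].to_numpy(),
                    float(proportions.at[ind, frac]))
        return cls(config=config, tree=tree, taxonomy=taxonomy, abundance=abundance,
                   proportions=proportions, propensities=propensities, offsets=offsets)


# ---------------------------------------------------------------------------
# sorting
# ---------------------------------------------------------------------------

@dataclass
class SortRecord:
    """Event tallies of one sorted gate for one individual."""

    tallies: np.ndarray  # per-taxon event counts, summing to sort_events
    n_in: int  # events whose true latent state is in-gate
    n_leak: int

    @property
    def purity(self) -> float:
        total = self.n_in + self.n_leak
        return self.n_in / total if total else np.nan


@dataclass
class SortedPool:
    """All sorted gates of a cohort: (individual, gate) -> SortRecord."""

    taxa: list[str]
    sort_events: int
    records: dict = field(default_factory=dict)

    def purity(self, individual: str, gate: str) -> float:
        return self.records[(individual, gate)].purity


def simulate_sorting(cohort: Cohort, config: SimConfig | None = None,
                     seed: int | None = None,
                     gates=("HNA", "LNA", "BONCATpos", "BONCATneg", "PIpos"),
                     individuals=None) -> SortedPool:
    """Sort `sort_events` events per gate per individual.

    Each event is in-gate with probability 1 - gate_error (drawn from the
    a_t * theta_t distribution) and a leaked out-of-gate cell otherwise.
    """
    config = config or cohort.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    pool = SortedPool(taxa=cohort.taxa, sort_events=config.sort_events)
    individuals = cohort.individuals if individuals is None else list(individuals)
    for ind in individuals:
        a = cohort.abundance.loc[ind].to_numpy()
        for gate in gates:
            theta = cohort.calibrated_theta(ind, gate)
            w_in = a * theta
            w_out = a * (1.0 - theta)
            if w_in.sum() <= 0:
                raise DegenerateFraction(f"no in-gate mass for {ind}/{gate}")
            err = config.gate_error.get(gate, 0.0)
            if w_out.sum() <= 0:
                err = 0.0  # nothing to leak
            n_in = int(rng.binomial(config.sort_events, 1.0 - err))
            n_leak = config.sort_events - n_in
            tallies = rng.multinomial(n_in, w_in / w_in.sum())
            if n_leak:
                tallies = tallies + rng.multinomial(n_leak, w_out / w_out.sum())
            pool.records[(ind, gate)] = SortRecord(tallies=tallies, n_in=n_in, n_leak=n_leak)
    return pool


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------

def _contaminant_ids(n: int) -> list[str]:
    return [f"ASVSHEATH{i + 1:02d}" for i in range(n)]


def contaminant_taxonomy(config: SimConfig) -> pd.DataFrame:
    ids = _contaminant_ids(config.n_contaminant_asvs)
    return pd.DataFrame({"domain": "Bacteria", "phylum": "Proteobacteria",
                         "genus": "Pseudomonas"}, index=ids)


def simulate_sequencing(pool: SortedPool, whole_composition: pd.DataFrame,
                        config: SimConfig, seed: int | None = None,
                        sample_prefix: str = "", treatment: str = "NA",
                        replicate: int = 1, include_sheath: bool = True,
                        metadata_individuals: dict | None = None) -> CountTable:
    """Multinomial amplicon libraries from sorted pools and Whole communities.

    Sorted samples receive contaminant reads (total uniform over
    sheath_read_range, split over the contaminant ASVs); Whole samples never
    contain contaminants; one sheath-only control is emitted per individual
    (one simulated sort day per individual).
    """
    if config.seq_depth <= 0:
        raise InvalidArgument("sequencing depth must be positive")
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    taxa = list(whole_composition.columns)
    contam = _contaminant_ids(config.n_contaminant_asvs)
    lo, hi = config.sheath_read_range
    counts_rows, meta_rows, ids = [], [], []

    def add(sample_id, vec_taxa, vec_contam, individual, fraction):
        ids.append(sample_id)
        counts_rows.append(np.concatenate([vec_taxa, vec_contam]))
        meta_rows.append({"individual": individual, "fraction": fraction,
                          "treatment": treatment, "replicate": replicate})

    individuals = list(whole_composition.index)
    suffix = f"_{sample_prefix}" if sample_prefix else ""
    for ind in individuals:
        a = whole_composition.loc[ind].to_numpy(dtype=float)
        add(f"{ind}_Whole{suffix}", rng.multinomial(config.seq_depth, a / a.sum()),
            np.zeros(len(contam), dtype=int), ind, "Whole")
    for (ind, gate), rec in pool.records.items():
        if ind not in set(individuals):
            continue
        p = rec.tallies / rec.tallies.sum()
        reads = rng.multinomial(config.seq_depth, p)
        c_total = int(rng.integers(lo, hi + 1))
        c_reads = rng.multinomial(c_total, np.full(len(contam), 1.0 / len(contam))) \
            if contam else np.zeros(0, dtype=int)
        add(f"{ind}_{gate}{suffix}", reads, c_reads, ind, gate)
    if include_sheath and contam:
        for ind in individuals:
            c_total = int(rng.integers(lo, hi + 1))
            c_reads = rng.multinomial(c_total, np.full(len(contam), 1.0 / len(contam)))
            add(f"{ind}_Sheath{suffix}", np.zeros(len(taxa), dtype=int), c_reads, ind, "Sheath")
    counts = pd.DataFrame(np.vstack(counts_rows), index=ids, columns=taxa + contam)
    meta = pd.DataFrame(meta_rows, index=ids)
    return CountTable(counts, meta)


# ---------------------------------------------------------------------------
# cytometry
# ---------------------------------------------------------------------------

def simulate_cytometry(proportions: pd.DataFrame, config: SimConfig,
                       seed: int | None = None, treatment: str = "NA",
                       replicate: int = 1, sample_suffix: str = "") -> CytometryCounts:
    """Gated event tallies reflecting latent proportions with binomial noise.

    HNA/LNA come from one SYBR acquisition (LNA = total - HNA); BONCAT+ and
    PI+ are scored against their own acquisition totals.
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    N = config.cyto_total_events
    rows = []
    for ind, row in proportions.iterrows():
        sample_id = f"{ind}{sample_suffix}"
        hna = int(rng.binomial(N, row["HNA"] / 100.0))
        for gate, events, total in (("HNA", hna, N), ("LNA", N - hna, N)):
            rows.append({"sample_id": sample_id, "individual": ind, "treatment": treatment,
                         "replicate": replicate, "gate": gate, "events": events,
                         "total_events": total})
        for gate in ("BONCATpos", "PIpos"):
            ev = int(rng.binomial(N, row[gate] / 100.0))
            rows.append({"sample_id": sample_id, "individual": ind, "treatment": treatment,
                         "replicate": replicate, "gate": gate, "events": ev,
                         "total_events": N})
    return CytometryCounts(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# xenobiotic treatments
# ---------------------------------------------------------------------------

def _moment_matched_truncnorm(mean: float, sd: float, size: int,
                              rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return np.full(size, mean)
    mu, sig = _truncnorm_latent(mean, sd)
    a, b = (_LO - mu) / sig, (_HI - mu) / sig
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sig, size=size, random_state=rng)


def simulate_treatments(cohort: Cohort, config: SimConfig | None = None,
                        seed: int | None = None):
    """Replicated xenobiotic incubations for the configured individuals.

    For each individual x treatment x replicate, fraction proportions are
    drawn around the treatment means, propensities recalibrated, and the full
    sorting + sequencing pipeline re-run. Returns (CountTable, CytometryCounts,
    proportions DataFrame of the latent per-replicate pi).
    """
    config = config or cohort.config
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    known = {"Control", "Digoxin", "Nizatidine", "Glucose"}
    tables, cyto_frames, truth_rows = [], [], []
    for ind_key, treatments in config.treatment_effects.items():
        if "Control" not in treatments:
            raise InvalidArgument(f"individual {ind_key}: treatments must include Control")
        unknown = set(treatments) - known
        if unknown:
            raise InvalidArgument(f"unknown treatment labels: {sorted(unknown)}")
        ind = ind_key if isinstance(ind_key, str) else f"I{ind_key:02d}"
        if ind not in set(cohort.individuals):
            raise InvalidArgument(f"individual {ind} not in cohort")
        a_row = cohort.abundance.loc[[ind]]
        for treat, effects in treatments.items():
            for rep in range(1, config.n_replicates + 1):
                pi = {}
                for frac in BASE_FRACTIONS:
                    mean, sd = effects.get(frac, (config.fraction_means[frac], 0.0))
                    pi[frac] = float(np.clip(
                        _moment_matched_truncnorm(mean, sd, 1, rng)[0], 1e-3, 100 - 1e-3))
                pi["LNA"] = 100.0 - pi["HNA"]
                props = pd.DataFrame([pi], index=[ind])[["HNA", "LNA", "BONCATpos", "PIpos"]]
                calibrate = (calibrate_activity_scale if config.calibration == "scale"
                             else calibrate_propensities)
                rep_cohort = Cohort(
                    config=config, tree=cohort.tree, taxonomy=cohort.taxonomy,
                    abundance=a_row, proportions=props,
                    propensities=cohort.propensities,
                    offsets=pd.DataFrame(
                        {frac: [calibrate(
                            a_row.iloc[0].to_numpy(),
                            cohort.propensities[frac].to_numpy(), pi[frac])]
                         for frac in BASE_FRACTIONS}, index=[ind]))
                pool = simulate_sorting(rep_cohort, config,
                                        seed=int(rng.integers(2 ** 31)))
                suffix = f"{treat}_r{rep}"
                table = simulate_sequencing(
                    pool, a_row, config, seed=int(rng.integers(2 ** 31)),
                    sample_prefix=suffix, treatment=treat, replicate=rep,
                    include_sheath=(rep == 1 and treat == "Control"))
                tables.append(table)
                cyto = simulate_cytometry(props, config, seed=int(rng.integers(2 ** 31)),
                                          treatment=treat, replicate=rep,
                                          sample_suffix=f"_{suffix}")
                cyto_frames.append(cyto.table)
                truth_rows.append({"individual": ind, "treatment": treat,
                                   "replicate": rep, **pi})
    counts = pd.concat([t.counts for t in tables])
    meta = pd.concat([t.metadata for t in tables])
    table = CountTable(counts.fillna(0).astype(int), meta)
    cytometry = CytometryCounts(pd.concat(cyto_frames, ignore_index=True))
    truth = pd.DataFrame(truth_rows)
    return table, cytometry, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Everything the analysis pipeline consumes, plus latent truth."""

    cohort: Cohort
    counts: CountTable
    cytometry: CytometryCounts
    taxonomy: pd.DataFrame
    tree: TreeNode
    truth: dict

    def write(self, out_dir) -> None:
        import pathlib

        import yaml

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.counts.to_csv(out / "counts.tsv", sep="\t", index_label="sample_id")
        self.counts.metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
        self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index_label="asv")
        self.tree.write(str(out / "tree.nwk"), format="newick")
        self.cytometry.table.to_csv(out / "cytometry.tsv", sep="\t", index=False)
        self.truth["proportions"].to_csv(out / "truth.tsv", sep="\t")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.cohort.config.to_dict(), fh, sort_keys=False)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Deterministic (given config.seed) simulation of a full cohort bundle."""
    ss = np.random.SeedSequence((config.seed, 17))
    s_sort, s_seq, s_cyto = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3))
    cohort = Cohort.make(config)
    pool = simulate_sorting(cohort, config, seed=s_sort)
    counts = simulate_sequencing(pool, cohort.abundance, config, seed=s_seq)
    cytometry = simulate_cytometry(cohort.proportions, config, seed=s_cyto)
    taxonomy = pd.concat([cohort.taxonomy, contaminant_taxonomy(config)])
    truth = {
        "proportions": cohort.proportions,
        "offsets": cohort.offsets,
        "contaminant_asvs": _contaminant_ids(config.n_contaminant_asvs),
        "purity": pd.Series({f"{i}_{g}": rec.purity
                             for (i, g), rec in pool.records.items()}),
    }
    return CohortBundle(cohort=cohort, counts=counts, cytometry=cytometry,
                        taxonomy=taxonomy, tree=cohort.tree, truth=truth)
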