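"""Codon substitution site models (M0, M1a, M2a, M7, M8) with maximum
likelihood fitting, likelihood-ratio tests, and empirical-Bayes
identification of positively selected sites.

The model family places a distribution of the nonsynonymous/synonymous rate
ratio omega across codon sites on a fixed tree.  M0 gives every site one
omega; M1a mixes a purifying class (0 < omega0 < 1) with a neutral class
(omega1 = 1); M2a adds a positive-selection class (omega2 >= 1); M7 draws
omega from a beta(p, q) on (0, 1), discretized into K equal-probability
categories; M8 adds a point mass at omegaS >= 1.  Positive selection is
inferred when M2a (or M8) fits significantly better than its nested null by
a chi-square LRT with 2 degrees of freedom, and individual sites are flagged
by the posterior probability of the omega > 1 class (naive empirical Bayes
at the MLEs by default, Bayes empirical Bayes over a class-parameter grid on
request).

The instantaneous rate between sense codons i != j is zero unless they
differ at exactly one position, otherwise pi_j * kappa^[transition] *
omega^[nonsynonymous] (the Goldman–Yang parameterization), normalized so
that branch lengths are expected substitutions per codon under the fitted
site-class mixture.

The surface follows the Model -> fit() -> Results convention:

>>> fit = CodonSiteModel(alignment, tree, model="M2a").fit(seed=1)
>>> fit.lnL, fit.params["omega2"]
>>> fit.selected_sites(threshold=0.95)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import codons
from .phylo import DistanceMatrix, Node, PhyloTree, neighbor_joining

N_STATES = len(codons.SENSE_CODONS)  # 61

MODELS = ("M0", "M1a", "M2a", "M7", "M8")
_POSITIVE_CLASS_MODELS = ("M2a", "M8")

_NESTED_PAIRS = {("M1a", "M2a"): 2, ("M7", "M8"): 2}


# ---------------------------------------------------------------------------
# rate matrix machinery
# ---------------------------------------------------------------------------

def _exchange_template() -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (ti, nonsyn) over single-step codon pairs; zero elsewhere
    encoded as -1 in a step mask."""
    step = np.zeros((N_STATES, N_STATES), dtype=bool)
    ti = np.zeros((N_STATES, N_STATES), dtype=bool)
    nonsyn = np.zeros((N_STATES, N_STATES), dtype=bool)
    for i, ci in enumerate(codons.SENSE_CODONS):
        for (_, old, new, mutant) in codons.single_step_neighbors(ci):
            j = codons.CODON_INDEX.get(mutant)
            if j is None:  # stop codon
                continue
            step[i, j] = True
            if codons.is_transition(old, new):
                ti[i, j] = True
            if codons.AMINO_ACID[ci] != codons.AMINO_ACID[mutant]:
                nonsyn[i, j] = True
    return step, ti, nonsyn


_STEP, _TI, _NONSYN = _exchange_template()


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Unscaled GY94 rate matrix Q and its mean rate r = -sum_i pi_i Q_ii."""
    Q = np.where(_STEP, pi[None, :], 0.0)
    Q = np.where(_TI, Q * kappa, Q)
    Q = np.where(_NONSYN, Q * omega, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    r = -float(np.dot(pi, np.diag(Q)))
    return Q, r


def transition_matrices(kappa, omega, pi, times, rate_scale):
    """P(t) for each t in ``times`` with generator Q/rate_scale, via the
    symmetric eigendecomposition of the reversible generator:
    P(t) = D^{-1/2} V e^{Lambda t} V' D^{1/2} with D = diag(pi)."""
    Q, _ = codon_rate_matrix(kappa, omega, pi)
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    out = np.empty((len(times), N_STATES, N_STATES))
    for k, t in enumerate(np.asarray(times, dtype=float)):
        M = (vecs * np.exp(vals * t / rate_scale)) @ vecs.T
        P = (M / sq[:, None]) * sq[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        out[k] = P
    return out


def codon_frequencies(seq_matrix: np.ndarray, mode: str = "f3x4") -> np.ndarray:
    """Equilibrium codon frequencies: 'equal', 'f1x4', or 'f3x4'."""
    if mode == "equal":
        return np.full(N_STATES, 1.0 / N_STATES)
    codon_strs = [codons.SENSE_CODONS[i] for i in seq_matrix.ravel()]
    if mode == "f1x4":
        counts = {nt: 1.0 for nt in "ACGT"}  # +1 smoothing
        for c in codon_strs:
            for nt in c:
                counts[nt] += 1
        tot = sum(counts.values())
        freq = {nt: counts[nt] / tot for nt in "ACGT"}
        pi = np.array([np.prod([freq[nt] for nt in c]) for c in codons.SENSE_CODONS])
    elif mode == "f3x4":
        counts = [{nt: 1.0 for nt in "ACGT"} for _ in range(3)]
        for c in codon_strs:
            for pos, nt in enumerate(c):
                counts[pos][nt] += 1
        freq = [
            {nt: counts[pos][nt] / sum(counts[pos].values()) for nt in "ACGT"}
            for pos in range(3)
        ]
        pi = np.array(
            [np.prod([freq[p][nt] for p, nt in enumerate(c)]) for c in codons.SENSE_CODONS]
        )
    else:
        raise ValueError(f"unknown codon frequency mode {mode!r}")
    return pi / pi.sum()


def discrete_beta(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of k equal-probability categories of a beta(p, q) distribution."""
    # equal-probability categories: edges are beta quantiles, and the mean
    # of category (a,b) is (p/(p+q)) * [I_b(p+1,q) - I_a(p+1,q)] * k
    edges = special.betaincinv(p, q, np.linspace(0.0, 1.0, k + 1))
    inc = special.betainc(p + 1.0, q, edges)
    means = (p / (p + q)) * np.diff(inc) * k
    return np.clip(means, 1e-8, 1.0 - 1e-8)


# ---------------------------------------------------------------------------
# model definition
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    """2*delta-lnL statistic, degrees of freedom, chi-square p-value."""

    delta: float
    df: int
    p: float
    null_model: str = ""
    alt_model: str = ""


def chi2_upper_tail(x: float, df: int) -> float:
    return float(stats.chi2.sf(x, df))


def likelihood_ratio_test(null_fit, alt_fit, df: int | None = None) -> LRTResult:
    """LRT between two nested site-model fits (M1a/M2a or M7/M8).

    The statistic 2(lnL_alt - lnL_null) is clamped at zero (optimizer noise)
    and referred to a chi-square upper tail.
    """
    pair = (null_fit.model, alt_fit.model)
    if df is None:
        if pair not in _NESTED_PAIRS:
            raise ValueError(f"models {pair} are not a supported nested pair")
        df = _NESTED_PAIRS[pair]
    delta = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    return LRTResult(delta=delta, df=df, p=chi2_upper_tail(delta, df),
                     null_model=pair[0], alt_model=pair[1])


class CodonSiteModel:
    """A codon site model bound to an in-frame, stop-free alignment and a tree.

    Parameters
    ----------
    alignment : mapping of name -> DNA sequence (equal lengths, multiple of 3
        after ``frame_offset`` trimming, no in-frame stop codons).
    tree : PhyloTree, newick string, or None (neighbor-joining tree from K80
        distances, the package default).
    model : one of M0, M1a, M2a, M7, M8.
    codon_freq : 'equal' | 'f1x4' | 'f3x4' (the usual CodeML-style default).
    """

    def __init__(
        self,
        alignment: dict[str, str],
        tree: PhyloTree | str | None = None,
        model: str = "M2a",
        codon_freq: str = "f3x4",
        n_beta_categories: int = 10,
        frame_offset: int = 0,
    ):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        self.model = model
        self.codon_freq_mode = codon_freq
        self.K = n_beta_categories
        self.names = list(alignment)
        seqs = {n: alignment[n][frame_offset:] for n in self.names}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("alignment sequences have unequal lengths")
        (L,) = lengths
        if L % 3:
            raise ValueError("alignment length is not a multiple of 3")
        mat = []
        for n in self.names:
            row = []
            for c in codons.codons_of(seqs[n]):
                if codons.is_stop(c):
                    raise ValueError(f"in-frame stop codon in sequence {n!r}")
                row.append(codons.CODON_INDEX[c])
            mat.append(row)
        self.seq_matrix = np.array(mat, dtype=int)  # taxa x sites
        self.n_sites = self.seq_matrix.shape[1]
        self.pi = codon_frequencies(self.seq_matrix, codon_freq)

        if tree is None:
            if len(self.names) < 3:
                raise ValueError("default NJ tree needs >= 3 sequences; pass a tree")
            dm = DistanceMatrix.from_sequences({n: seqs[n] for n in self.names})
            tree = neighbor_joining(dm)
        elif isinstance(tree, str):
            tree = PhyloTree.from_newick(tree)
        tips = set(tree.tip_names())
        if tips != set(self.names):
            raise ValueError(
                f"tree tips {sorted(tips)} do not match sequence names {sorted(self.names)}"
            )
        self.tree = tree
        # flatten tree into postorder edge arrays once
        self._post = self.tree.postorder()
        self._node_ids = {id(n): k for k, n in enumerate(self._post)}
        self._edges = [n for n in self._post if n is not self.tree.root]
        self._edge_index = {id(n): k for k, n in enumerate(self._edges)}
        # site patterns
        patterns, inverse, counts = np.unique(
            self.seq_matrix, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # taxa x n_patterns
        self.pattern_weights = counts.astype(float)
        self._pattern_of_site = inverse

    # -- mixture definition -------------------------------------------------

    def site_classes(self, params: dict) -> tuple[np.ndarray, np.ndarray]:
        """(omega values, proportions) of the site-class mixture."""
        m = self.model
        if m == "M0":
            return np.array([params["omega"]]), np.array([1.0])
        if m == "M1a":
            p0 = params["p0"]
            return np.array([params["omega0"], 1.0]), np.array([p0, 1.0 - p0])
        if m == "M2a":
            return (
                np.array([params["omega0"], 1.0, params["omega2"]]),
                np.array([params["p0"], params["p1"], params["p2"]]),
            )
        if m == "M7":
            w = discrete_beta(params["p"], params["q"], self.K)
            return w, np.full(self.K, 1.0 / self.K)
        if m == "M8":
            w = discrete_beta(params["p"], params["q"], self.K)
            p0 = params["p0"]
            return (
                np.append(w, params["omega_s"]),
                np.append(np.full(self.K, p0 / self.K), 1.0 - p0),
            )
        raise AssertionError(m)

    # -- likelihood ---------------------------------------------------------

    def _branch_lengths(self) -> np.ndarray:
        return np.array([e.length for e in self._edges], dtype=float)

    def class_site_loglikes(
        self, blens: np.ndarray, kappa: float, omegas: np.ndarray, rate_scale: float
    ) -> np.ndarray:
        """log f(pattern | omega_k) for each class k: (K, n_patterns)."""
        n_pat = self.patterns.shape[1]
        out = np.empty((len(omegas), n_pat))
        for k, w in enumerate(omegas):
            P = transition_matrices(kappa, w, self.pi, blens, rate_scale)
            partial = {}  # node rank -> (n_pat, 61)
            logscale = np.zeros(n_pat)
            for node in self._post:
                if node.is_tip():
                    continue
                acc = np.ones((n_pat, N_STATES))
                for ch in node.children:
                    Pb = P[self._edge_index[id(ch)]]
                    if ch.is_tip():
                        ti = self.names.index(ch.name)
                        acc *= Pb[:, self.patterns[ti]].T
                    else:
                        acc *= partial.pop(self._node_ids[id(ch)]) @ Pb.T
                mx = acc.max(axis=1)
                mx[mx == 0] = 1.0
                acc /= mx[:, None]
                logscale += np.log(mx)
                partial[self._node_ids[id(node)]] = acc
            root = partial[self._node_ids[id(self.tree.root)]]
            site_like = root @ self.pi
            out[k] = np.log(np.clip(site_like, 1e-300, None)) + logscale
        return out

    def loglike(self, params: dict, blens: np.ndarray | None = None) -> float:
        """Mixture log-likelihood at the given parameter values."""
        omegas, props = self.site_classes(params)
        _, rates = zip(*(codon_rate_matrix(params["kappa"], w, self.pi) for w in omegas))
        rate_scale = float(np.dot(props, rates))
        if rate_scale <= 0:
            return -np.inf
        if blens is None:
            blens = self._branch_lengths()
        csl = self.class_site_loglikes(blens, params["kappa"], omegas, rate_scale)
        # logsumexp over classes with weights
        mx = csl.max(axis=0)
        site_ln = mx + np.log(np.clip((props[:, None] * np.exp(csl - mx)).sum(axis=0), 1e-300, None))
        return float(np.dot(self.pattern_weights, site_ln))

    # -- optimization -------------------------------------------------------

    def _param_spec(self):
        """(names, defaults, bounds) of the free model parameters; simplex
        proportions of M2a travel as two unconstrained stick variables."""
        m = self.model
        if m == "M0":
            return ["kappa", "omega"], [2.0, 0.4], [(0.1, 20), (1e-4, 50)]
        if m == "M1a":
            return (
                ["kappa", "p0", "omega0"],
                [2.0, 0.7, 0.1],
                [(0.1, 20), (1e-6, 1 - 1e-6), (1e-4, 1.0)],
            )
        if m == "M2a":
            return (
                ["kappa", "a0", "a1", "omega0", "omega2"],
                [2.0, 1.0, 0.5, 0.1, 3.0],
                [(0.1, 20), (-15, 15), (-15, 15), (1e-4, 1.0), (1.0, 50)],
            )
        if m == "M7":
            return ["kappa", "p", "q"], [2.0, 0.5, 1.0], [(0.1, 20), (0.005, 99), (0.005, 99)]
        if m == "M8":
            return (
                ["kappa", "p0", "p", "q", "omega_s"],
                [2.0, 0.85, 0.5, 1.0, 3.0],
                [(0.1, 20), (1e-6, 1 - 1e-6), (0.005, 99), (0.005, 99), (1.0, 50)],
            )
        raise AssertionError(m)

    def _decode(self, names: list[str], x: np.ndarray) -> dict:
        params = dict(zip(names, x))
        if self.model == "M2a":
            e = np.exp([params.pop("a0"), params.pop("a1"), 0.0])
            p = e / e.sum()
            params["p0"], params["p1"], params["p2"] = p
        return params

    def fit(
        self,
        restarts: int = 5,
        seed: int = 0,
        optimize_branch_lengths: str = "scale",
        tol: float = 1e-8,
        start: dict | None = None,
    ) -> "CodonSiteModelResults":
        """Maximize the likelihood by multi-start bounded quasi-Newton search.

        ``optimize_branch_lengths``: 'scale' (default) first estimates branch
        lengths under M0, then co-estimates one overall tree-scale factor
        with the site-model parameters; 'full' co-estimates every branch
        length; 'fixed' keeps the input branch lengths.
        """
        if optimize_branch_lengths not in ("scale", "full", "fixed"):
            raise ValueError(f"unknown branch mode {optimize_branch_lengths!r}")
        rng = np.random.default_rng(seed)
        base_blens = self._branch_lengths()
        if optimize_branch_lengths == "scale" and self.model != "M0":
            m0 = CodonSiteModel.__new__(CodonSiteModel)
            m0.__dict__.update(self.__dict__)
            m0.model = "M0"
            m0_fit = m0.fit(
                restarts=1, seed=seed, optimize_branch_lengths="full", tol=tol
            )
            base_blens = m0_fit.branch_lengths
        base_blens = np.clip(base_blens, 1e-6, None)

        names, defaults, bounds = self._param_spec()
        nb = {
            "fixed": 0,
            "scale": 1,
            "full": len(self._edges),
        }[optimize_branch_lengths]
        if optimize_branch_lengths == "scale":
            bbounds = [(1e-3, 1e3)]
            bdefault = [1.0]
        elif optimize_branch_lengths == "full":
            bbounds = [(1e-8, 50.0)] * nb
            bdefault = list(base_blens)
        else:
            bbounds, bdefault = [], []

        def objective(x):
            bx, px = x[:nb], x[nb:]
            if optimize_branch_lengths == "scale":
                blens = base_blens * bx[0]
            elif optimize_branch_lengths == "full":
                blens = bx
            else:
                blens = base_blens
            params = self._decode(names, px)
            try:
                return -self.loglike(params, blens)
            except (FloatingPointError, np.linalg.LinAlgError):
                return 1e10

        x0s = [np.array(bdefault + defaults)]
        if start is not None:
            sx = [start.get(n, d) for n, d in zip(names, defaults)]
            x0s.insert(0, np.array(bdefault + sx))
        lo = np.array([b[0] for b in bbounds + bounds])
        hi = np.array([b[1] for b in bbounds + bounds])
        for _ in range(max(0, restarts - 1)):
            jit = x0s[0] * np.exp(rng.normal(0, 0.4, size=len(x0s[0])))
            x0s.append(np.clip(jit, lo, hi))

        best = None
        n_converged = 0
        for x0 in x0s:
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bbounds + bounds,
                options={"ftol": tol, "maxiter": 500},
            )
            n_converged += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        bx, px = best.x[:nb], best.x[nb:]
        if optimize_branch_lengths == "scale":
            blens = base_blens * bx[0]
        elif optimize_branch_lengths == "full":
            blens = bx
        else:
            blens = base_blens
        params = self._decode(names, px)
        lnL = -best.fun
        return CodonSiteModelResults(
            model=self.model,
            _mod=self,
            params=params,
            lnL=float(lnL),
            branch_lengths=np.asarray(blens, dtype=float),
            converged=bool(n_converged),
            n_restarts=len(x0s),
        )


@dataclass
class CodonSiteModelResults:
    """MLEs, log-likelihood, and per-site posteriors of a fitted site model."""

    model: str
    _mod: CodonSiteModel = field(repr=False)
    params: dict = field(default_factory=dict)
    lnL: float = np.nan
    branch_lengths: np.ndarray | None = None
    converged: bool = True
    n_restarts: int = 0

    # -- posteriors ---------------------------------------------------------

    def _class_loglikes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mod = self._mod
        omegas, props = mod.site_classes(self.params)
        _, rates = zip(
            *(codon_rate_matrix(self.params["kappa"], w, mod.pi) for w in omegas)
        )
        scale = float(np.dot(props, rates))
        csl = mod.class_site_loglikes(
            self.branch_lengths, self.params["kappa"], omegas, scale
        )
        return omegas, props, csl

    def site_posteriors(self) -> pd.DataFrame:
        """Naive empirical Bayes posterior of each omega class at every site
        (rows sum to 1)."""
        mod = self._mod
        omegas, props, csl = self._class_loglikes()
        logw = np.log(np.clip(props, 1e-300, None))[:, None] + csl
        logw -= special.logsumexp(logw, axis=0, keepdims=True)
        post = np.exp(logw)[:, mod._pattern_of_site].T  # sites x classes
        return pd.DataFrame(
            post,
            index=pd.RangeIndex(1, mod.n_sites + 1, name="site"),
            columns=[f"omega={w:.4g}" for w in omegas],
        )

    def positive_class_posterior(self, method: str = "NEB") -> np.ndarray:
        """Posterior probability, per site, of the omega > 1 class."""
        if self.model not in _POSITIVE_CLASS_MODELS:
            raise ValueError(
                f"model {self.model} has no positive-selection class"
            )
        if method == "NEB":
            return self.site_posteriors().to_numpy()[:, -1]
        if method == "BEB":
            return self._beb_posterior()
        raise ValueError(f"unknown site-identification method {method!r}")

    def _beb_posterior(self, grid: int = 10) -> np.ndarray:
        """Bayes empirical Bayes over the positive-class parameter grid.

        M2a: uniform prior over (p0, p1) on the triangle grid, omega0 on
        (0,1), omega2 on (1,11), each with ``grid`` points; kappa and branch
        lengths fixed at their MLEs.  M8: grid over p0 and omegaS with the
        beta(p, q) shape fixed at its MLE.
        """
        mod = self._mod
        kappa = self.params["kappa"]
        omegas_mle, props_mle, _ = self._class_loglikes()
        scale = float(
            np.dot(props_mle, [codon_rate_matrix(kappa, w, mod.pi)[1] for w in omegas_mle])
        )
        pts = (np.arange(grid) + 0.5) / grid  # 0.05 .. 0.95

        def site_ll(omega_values: np.ndarray) -> np.ndarray:
            return mod.class_site_loglikes(
                self.branch_lengths, kappa, np.asarray(omega_values), scale
            )

        if self.model == "M2a":
            w0_vals = pts
            w2_vals = 1.0 + 10.0 * pts
            ll0 = site_ll(w0_vals)       # grid x patterns
            ll1 = site_ll(np.array([1.0]))[0]
            ll2 = site_ll(w2_vals)
            thetas = []
            for p0, p1 in itertools.product(pts, pts):
                if p0 + p1 > 1.0 + 1e-9:
                    continue
                thetas.append((p0, p1, 1.0 - p0 - p1))
            lse = special.logsumexp
            cells = []
            for (p0, p1, p2) in thetas:
                for i0 in range(grid):
                    for i2 in range(grid):
                        cells.append((p0, p1, p2, i0, i2))
            # vectorized over cells
            n_pat = ll1.shape[0]
            total = np.empty(len(cells))
            frac2 = np.empty((len(cells), n_pat))
            for c, (p0, p1, p2, i0, i2) in enumerate(cells):
                stack = np.stack([ll0[i0], ll1, ll2[i2]])
                mix = lse(
                    stack + np.log(np.clip([p0, p1, p2], 1e-300, None))[:, None], axis=0
                )
                total[c] = float(np.dot(mod.pattern_weights, mix))
                with np.errstate(divide="ignore"):
                    frac2[c] = np.exp(np.log(max(p2, 1e-300)) + ll2[i2] - mix)
            total -= lse(total)
            post_pat = np.exp(total) @ frac2
        elif self.model == "M8":
            p, q = self.params["p"], self.params["q"]
            beta_w = discrete_beta(p, q, mod.K)
            ll_beta = site_ll(beta_w)
            ws_vals = 1.0 + 10.0 * pts
            ll_s = site_ll(ws_vals)
            lse = special.logsumexp
            cells = list(itertools.product(range(grid), range(grid)))  # (p0, ws)
            n_pat = ll_beta.shape[1]
            total = np.empty(len(cells))
            frac2 = np.empty((len(cells), n_pat))
            for c, (ip, iw) in enumerate(cells):
                p0 = pts[ip]
                mix_beta = lse(ll_beta + np.log(p0 / mod.K), axis=0)
                stack = np.stack([mix_beta, ll_s[iw] + np.log(1.0 - p0)])
                mix = lse(stack, axis=0)
                total[c] = float(np.dot(mod.pattern_weights, mix))
                frac2[c] = np.exp(ll_s[iw] + np.log(1.0 - p0) - mix)
            total -= lse(total)
            post_pat = np.exp(total) @ frac2
        else:  # pragma: no cover - guarded by positive_class_posterior
            raise AssertionError(self.model)
        return post_pat[mod._pattern_of_site]

    def selected_sites(
        self, threshold: float = 0.95, method: str = "NEB"
    ) -> pd.DataFrame:
        """Sites whose posterior of the positive class exceeds ``threshold``.

        Returns a DataFrame with 1-based site index and the posterior.
        """
        post = self.positive_class_posterior(method=method)
        sites = np.nonzero(post > threshold)[0] + 1
        return pd.DataFrame(
            {"site": sites, "posterior": post[sites - 1]}
        ).set_index("site")

    # -- reporting ----------------------------------------------------------

    def lrt(self, null_fit: "CodonSiteModelResults", df: int | None = None) -> LRTResult:
        return likelihood_ratio_test(null_fit, self, df=df)

    def summary(self) -> str:
        lines = [
            f"Codon site model {self.model}",
            f"  lnL          {self.lnL:.4f}",
            f"  converged    {self.converged} ({self.n_restarts} starts)",
            f"  tree length  {float(np.sum(self.branch_lengths)):.4f}",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:<12} {v:.4f}")
        omegas, props = self._mod.site_classes(self.params)
        lines.append(
            "  classes      "
            + ", ".join(f"omega={w:.3f} (p={p:.3f})" for w, p in zip(omegas, props))
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        omegas, props = self._mod.site_classes(self.params)
        return {
            "model": self.model,
            "lnL": self.lnL,
            "params": {k: float(v) for k, v in self.params.items()},
            "class_omegas": [float(w) for w in omegas],
            "class_proportions": [float(p) for p in props],
            "tree_length": float(np.sum(self.branch_lengths)),
            "converged": self.converged,
        }


def fit_site_model(
    alignment: dict[str, str],
    tree: PhyloTree | str | None = None,
    model: str = "M2a",
    codon_freq: str = "f3x4",
    restarts: int = 5,
    seed: int = 0,
    **kwargs,
) -> CodonSiteModelResults:
    """Convenience wrapper: build the model and fit it."""
    return CodonSiteModel(alignment, tree=tree, model=model, codon_freq=codon_freq).fit(
        restarts=restarts, seed=seed, **kwargs
    )


def identify_selected_sites(
    fit: CodonSiteModelResults, threshold: float = 0.95, method: str = "NEB"
) -> pd.DataFrame:
    """Positively selected sites of an M2a/M8 fit at the given posterior
    threshold (errors for models without an omega > 1 class)."""
    return fit.selected_sites(threshold=threshold, method=method)
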