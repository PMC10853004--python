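"""Marginal (empirical-Bayes) ancestral sequence reconstruction.

Given a rooted tree with branch lengths (expected substitutions per site)
and a gapped alignment, this module computes per-site likelihoods by
Felsenstein's pruning algorithm and per-node marginal posterior state
distributions, for an arbitrary reversible substitution model.  Length
variable regions are handled by the standard binary recoding: every residue
becomes "present" (1) and every gap "absent" (0), and presence is
reconstructed under a two-state general time-reversible model.  An
ancestral sequence estimate reports, per site, the maximum-a-posteriori
residue with its posterior probability, gated on the posterior probability
that a residue is present at all.

Branch lengths are taken as given; this is a reconstruction engine, not a
tree or branch-length estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "SubstitutionModel",
    "SitePosterior",
    "AncestralSequenceEstimate",
    "ReplacementList",
    "load_tree",
    "site_likelihood",
    "site_log_likelihoods",
    "marginal_states",
    "binary_recode",
    "presence_posteriors",
    "estimate_ancestral_sequence",
    "diff_replacements",
    "discrete_gamma_rates",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
MISSING_CHARS = {"-", ".", "?", "X"}


class SubstitutionModel:
    """A reversible continuous-time substitution model.

    ``rate_matrix`` Q has non-negative off-diagonals, zero row sums, and is
    normalised to one expected substitution per unit branch length at
    stationarity.  Transition matrices P(t) = exp(Qt) are computed through
    the symmetrised eigendecomposition available for reversible models.
    """

    def __init__(self, alphabet: Sequence[str], rate_matrix, freqs):
        self.alphabet = tuple(alphabet)
        k = len(self.alphabet)
        Q = np.asarray(rate_matrix, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        if Q.shape != (k, k):
            raise ValueError(f"rate matrix must be {k}x{k}")
        if pi.shape != (k,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a distribution over the alphabet")
        if np.any(pi <= 0):
            raise ValueError("all stationary frequencies must be positive")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to zero")
        flux = pi[:, None] * Q
        if not np.allclose(flux, flux.T, atol=1e-10):
            raise ValueError("model is not reversible (detailed balance fails)")
        self.rate_matrix = Q
        self.freqs = pi
        # symmetrise: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U / d[:, None]  # D^{-1/2} U
        self._right = U.T * d[None, :]  # U^T D^{1/2}

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, P(0) is the identity."""
        if t < 0 or not np.isfinite(t):
            raise ValueError("branch length must be finite and non-negative")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        return np.clip(P, 0.0, None)

    @classmethod
    def equal_rates(cls, alphabet: Sequence[str] = AMINO_ACIDS, freqs=None):
        """Equal exchangeabilities; substitution flux proportional to the
        target frequency (the F81-style model; Jukes–Cantor-like when the
        frequencies are uniform)."""
        k = len(alphabet)
        pi = np.full(k, 1.0 / k) if freqs is None else np.asarray(freqs, dtype=float)
        S = np.ones((k, k)) - np.eye(k)
        return cls.from_exchangeabilities(S, pi, alphabet)

    @classmethod
    def binary(cls, pi_present: float = 0.5):
        """Two-state general time-reversible model over {absent, present}."""
        if not 0 < pi_present < 1:
            raise ValueError("pi_present must be in (0, 1)")
        return cls.from_exchangeabilities(
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.array([1.0 - pi_present, pi_present]),
            ("0", "1"),
        )

    @classmethod
    def from_exchangeabilities(cls, S, freqs, alphabet: Sequence[str] = AMINO_ACIDS):
        """Build Q from a symmetric exchangeability matrix and frequencies.

        Empirical matrices (e.g. JTT) are supplied as data files; see
        :func:`load_exchangeability_file`.
        """
        S = np.asarray(S, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()  # expected rate at stationarity
        if mu <= 0:
            raise ValueError("degenerate exchangeability matrix")
        return cls(alphabet, Q / mu, pi)


def load_exchangeability_file(path, alphabet: Sequence[str] = AMINO_ACIDS):
    """Read a plain-text lower-triangular exchangeability matrix plus a
    frequency line (PAML .dat layout) and return a SubstitutionModel."""
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            values.extend(float(x) for x in line.split())
    k = len(alphabet)
    n_tri = k * (k - 1) // 2
    if len(values) < n_tri + k:
        raise ValueError(
            f"expected at least {n_tri + k} numbers (triangle + frequencies)"
        )
    S = np.zeros((k, k))
    it = iter(values[:n_tri])
    for i in range(1, k):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    freqs = np.asarray(values[n_tri : n_tri + k])
    return SubstitutionModel.from_exchangeabilities(S, freqs, alphabet)


def discrete_gamma_rates(alpha: float, n_categories: int) -> list[tuple[float, float]]:
    """Equal-weight discrete-gamma rate categories (mean-of-quantile bins)."""
    if alpha <= 0 or n_categories < 1:
        raise ValueError("alpha must be positive and n_categories >= 1")
    probs = (np.arange(n_categories) + 0.5) / n_categories
    rates = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
    rates = rates / rates.mean()
    w = 1.0 / n_categories
    return [(float(r), w) for r in rates]


@dataclass(frozen=True)
class SitePosterior:
    node: str
    site: int  # 1-based alignment column
    probabilities: tuple[float, ...]
    alphabet: tuple[str, ...]

    @property
    def map_state(self) -> str:
        return self.alphabet[int(np.argmax(self.probabilities))]

    @property
    def map_probability(self) -> float:
        return float(max(self.probabilities))


@dataclass(frozen=True)
class AncestralSequenceEstimate:
    """Per-site MAP residues with posteriors, gated on residue presence."""

    node: str
    map_states: tuple[str, ...]
    map_posteriors: tuple[float, ...]
    presence_posteriors: tuple[float, ...] | None = None
    presence_threshold: float = 0.5

    def present(self, site_index: int) -> bool:
        """Is a residue estimated present at 0-based ``site_index``?
        Ties at the threshold break toward presence."""
        if self.presence_posteriors is None:
            return True
        return self.presence_posteriors[site_index] >= self.presence_threshold

    @property
    def sequence(self) -> str:
        return "".join(
            s if self.present(i) else "-" for i, s in enumerate(self.map_states)
        )


@dataclass(frozen=True)
class ReplacementList:
    replacements: tuple[tuple[int, str, str, float, float], ...]
    indels: tuple[tuple[int, str], ...]

    def __len__(self) -> int:
        return len(self.replacements)


# ---------------------------------------------------------------------------
# tree and alignment plumbing


def load_tree(source) -> dendropy.Tree:
    """Load a rooted newick tree (path, newick text, or dendropy Tree)."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" not in text:
        tree = dendropy.Tree.get(path=text, schema="newick")
    else:
        tree = dendropy.Tree.get(data=text, schema="newick")
    return tree


def _node_name(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def _as_sequences(alignment) -> dict[str, str]:
    if isinstance(alignment, Mapping):
        return {str(k): str(v) for k, v in alignment.items()}
    if isinstance(alignment, (str, Path)):
        alignment = AlignIO.read(str(alignment), "fasta")
    return {rec.id: str(rec.seq) for rec in alignment}


def _encode(seq: str, alphabet: Sequence[str]) -> np.ndarray:
    index = {a: i for i, a in enumerate(alphabet)}
    codes = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        if c in index:
            codes[i] = index[c]
        elif c in MISSING_CHARS:
            codes[i] = -1
        else:
            raise ValueError(f"state symbol {c!r} not in model alphabet")
    return codes


# ---------------------------------------------------------------------------
# pruning engine


class _Pruned:
    """Inside/outside partial likelihoods for one rate class over all sites."""

    def __init__(self, tree, codes: Mapping[str, np.ndarray], model, rate=1.0):
        self.tree = tree
        self.model = model
        k = model.n_states
        n_sites = len(next(iter(codes.values())))
        self.n_sites = n_sites
        self.inside: dict[int, np.ndarray] = {}
        self.logscale: dict[int, np.ndarray] = {}
        self.P: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.parent_node is not None:
                t = node.edge.length or 0.0
                self.P[id(node)] = model.transition_matrix(t * rate)
            if node.is_leaf():
                name = _node_name(node)
                if name not in codes:
                    raise KeyError(f"no sequence for leaf {name!r}")
                c = codes[name]
                L = np.ones((n_sites, k))
                obs = c >= 0
                L[obs] = 0.0
                L[obs, c[obs]] = 1.0
                self.inside[id(node)] = L
                self.logscale[id(node)] = np.zeros(n_sites)
            else:
                L = np.ones((n_sites, k))
                ls = np.zeros(n_sites)
                for child in node.child_nodes():
                    L = L * (self.inside[id(child)] @ self.P[id(child)].T)
                    ls = ls + self.logscale[id(child)]
                m = L.max(axis=1)
                m[m == 0] = 1.0
                self.inside[id(node)] = L / m[:, None]
                self.logscale[id(node)] = ls + np.log(m)
        self.root = tree.seed_node

    def site_log_likelihoods(self) -> np.ndarray:
        root_in = self.inside[id(self.root)]
        lik = root_in @ self.model.freqs
        return np.log(lik) + self.logscale[id(self.root)]

    def downward(self) -> dict[int, np.ndarray]:
        """Per-node outside vectors; posterior ∝ down * inside per site."""
        if getattr(self, "_down", None) is not None:
            return self._down
        down: dict[int, np.ndarray] = {
            id(self.root): np.broadcast_to(
                self.model.freqs, (self.n_sites, self.model.n_states)
            ).copy()
        }
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            msgs = [self.inside[id(c)] @ self.P[id(c)].T for c in children]
            for i, child in enumerate(children):
                above = down[id(node)].copy()
                for j, m in enumerate(msgs):
                    if j != i:
                        above = above * m
                d = above @ self.P[id(child)]
                mx = d.max(axis=1)
                mx[mx == 0] = 1.0
                down[id(child)] = d / mx[:, None]
        self._down = down
        return down

    def posterior(self, node) -> np.ndarray:
        down = self.downward()
        joint = down[id(node)] * self.inside[id(node)]
        total = joint.sum(axis=1, keepdims=True)
        if np.any(total == 0):
            raise ValueError("zero site likelihood; data impossible under model")
        return joint / total


def _find_node(tree, label: str):
    for node in tree.preorder_node_iter():
        if _node_name(node) == label:
            return node
    raise KeyError(f"node {label!r} not found in tree")


def _prepare(tree, alignment, model):
    t = load_tree(tree)
    seqs = _as_sequences(alignment)
    codes = {name: _encode(s, model.alphabet) for name, s in seqs.items()}
    lengths = {len(c) for c in codes.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    return t, codes


def site_log_likelihoods(
    tree, alignment, model: SubstitutionModel, rates=None
) -> np.ndarray:
    """Log-likelihood of every alignment column under the model.

    ``rates`` is an optional list of (rate, weight) categories (see
    :func:`discrete_gamma_rates`); the site likelihood is then the weighted
    average over categories.
    """
    t, codes = _prepare(tree, alignment, model)
    if not rates:
        return _Pruned(t, codes, model).site_log_likelihoods()
    per_cat = np.stack(
        [_Pruned(t, codes, model, rate=r).site_log_likelihoods() for r, _ in rates]
    )
    w = np.log(np.array([w for _, w in rates]))[:, None]
    from scipy.special import logsumexp

    return logsumexp(per_cat + w, axis=0)


def site_likelihood(
    tree, column: Mapping[str, str], model: SubstitutionModel, rates=None
) -> float:
    """Likelihood of a single column given as a leaf→state mapping.

    Gaps and ``?`` are treated as missing data (partial likelihood of one
    in every state).
    """
    alignment = {leaf: state for leaf, state in column.items()}
    ll = site_log_likelihoods(tree, alignment, model, rates=rates)
    return float(np.exp(ll[0]))


def marginal_states(
    tree, alignment, model: SubstitutionModel, node: str, rates=None
) -> list[SitePosterior]:
    """Marginal posterior state distribution at ``node`` for every site.

    The posterior at the node is proportional to the partial likelihood of
    the data below it times the likelihood of the rest of the tree routed
    through it, with the root prior given by the stationary frequencies;
    with rate categories it is the likelihood-weighted mixture across
    categories.
    """
    t, codes = _prepare(tree, alignment, model)
    target = _find_node(t, node)
    if target.is_leaf():
        raise ValueError(f"node {node!r} is a leaf; reconstruction targets are internal")
    post = _marginal_posterior_matrix(t, codes, model, target, rates)
    return [
        SitePosterior(node, s + 1, tuple(post[s]), model.alphabet)
        for s in range(post.shape[0])
    ]


def _marginal_posterior_matrix(t, codes, model, target, rates=None) -> np.ndarray:
    if not rates:
        return _Pruned(t, codes, model).posterior(target)
    engines = [(_Pruned(t, codes, model, rate=r), w) for r, w in rates]
    return _mixture_posterior(engines, target)


GAP_ONLY = {"-", "."}


def binary_recode(alignment) -> tuple[np.ndarray, list[str]]:
    """Recode a gapped alignment to presence/absence: residue→1, gap→0."""
    seqs = _as_sequences(alignment)
    names = list(seqs)
    matrix = np.array(
        [[0 if c in GAP_ONLY else 1 for c in seqs[n]] for n in names], dtype=np.int8
    )
    return matrix, names


def presence_posteriors(
    tree,
    alignment_or_matrix,
    model: SubstitutionModel | None = None,
    names: Sequence[str] | None = None,
    rates=None,
) -> dict[str, np.ndarray]:
    """Posterior probability that a residue is present, per internal node
    and site, under a two-state model on the binary recoding."""
    model = model or SubstitutionModel.binary()
    if model.n_states != 2:
        raise ValueError("presence reconstruction requires a two-state model")
    if isinstance(alignment_or_matrix, np.ndarray):
        if names is None:
            raise ValueError("names must accompany a raw binary matrix")
        seqs = {
            n: "".join(str(int(b)) for b in row)
            for n, row in zip(names, alignment_or_matrix)
        }
    else:
        matrix, mnames = binary_recode(alignment_or_matrix)
        seqs = {n: "".join(str(int(b)) for b in row) for n, row in zip(mnames, matrix)}
    t, codes = _prepare(tree, seqs, model)
    engines = [
        (_Pruned(t, codes, model, rate=r), w) for r, w in (rates or [(1.0, 1.0)])
    ]
    out: dict[str, np.ndarray] = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        label = _node_name(node)
        if label is None:
            continue
        if len(engines) == 1:
            post = engines[0][0].posterior(node)
        else:
            post = _mixture_posterior(engines, node)
        out[label] = post[:, 1]
    return out


def _mixture_posterior(engines, target) -> np.ndarray:
    posts, liks = [], []
    for eng, w in engines:
        down = eng.downward()
        joint = down[id(target)] * eng.inside[id(target)]
        posts.append(joint / joint.sum(axis=1, keepdims=True))
        liks.append(np.exp(eng.site_log_likelihoods()) * w)
    liks = np.stack(liks)
    weights = liks / liks.sum(axis=0, keepdims=True)
    return np.einsum("cs,csk->sk", weights, np.stack(posts))


def estimate_ancestral_sequence(
    tree,
    alignment,
    model: SubstitutionModel,
    node: str,
    binary_model: SubstitutionModel | None = None,
    presence_threshold: float = 0.5,
    rates=None,
) -> AncestralSequenceEstimate:
    """MAP ancestral sequence at ``node`` with presence gating.

    Residue posteriors come from the amino-acid (or nucleotide) model on
    the original alignment; presence posteriors come from the two-state
    model on the binary recoding.  A residue is reported only where its
    presence posterior reaches ``presence_threshold`` (ties toward
    presence).
    """
    posts = marginal_states(tree, alignment, model, node, rates=rates)
    presence = presence_posteriors(tree, alignment, binary_model, rates=rates)
    if node not in presence:
        raise KeyError(f"node {node!r} not found for presence reconstruction")
    return AncestralSequenceEstimate(
        node=node,
        map_states=tuple(p.map_state for p in posts),
        map_posteriors=tuple(p.map_probability for p in posts),
        presence_posteriors=tuple(float(x) for x in presence[node]),
        presence_threshold=presence_threshold,
    )


def diff_replacements(
    anc: AncestralSequenceEstimate, desc: AncestralSequenceEstimate
) -> ReplacementList:
    """Amino-acid replacements between two ancestral estimates.

    A replacement is a site where both nodes have a residue present and
    their MAP states differ; sites where presence flips are reported
    separately as insertions (gained in the descendant) or deletions.
    """
    if len(anc.map_states) != len(desc.map_states):
        raise ValueError("estimates cover different numbers of alignment columns")
    repl, indels = [], []
    for i in range(len(anc.map_states)):
        a_here, d_here = anc.present(i), desc.present(i)
        if a_here and d_here:
            if anc.map_states[i] != desc.map_states[i]:
                repl.append(
                    (
                        i + 1,
                        anc.map_states[i],
                        desc.map_states[i],
                        anc.map_posteriors[i],
                        desc.map_posteriors[i],
                    )
                )
        elif a_here and not d_here:
            indels.append((i + 1, "deletion"))
        elif d_here and not a_here:
            indels.append((i + 1, "insertion"))
    return ReplacementList(tuple(repl), tuple(indels))
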