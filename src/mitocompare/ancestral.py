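"""Ancestral reconstruction of discrete mitogenomic characters on a phylogeny.

A single character (e.g., the gene-arrangement pattern letter, or the
nad2/nad3 joining-state letter) observed at the tips of a rooted tree with
branch lengths is modelled under the k-state equal-rates Markov (Mk) model:

    P(i -> j, t) = 1/k + (delta_ij - 1/k) * exp(-k * r * t / (k - 1))

with a uniform root prior.  The API follows the statsmodels convention:
``MkModel(tree, states).fit()`` returns an :class:`MkResults` carrying the
maximum-likelihood rate, the log-likelihood, per-node marginal state
probabilities ("occurrences" when expressed as percentages), and a
``summary()`` table.  Multifurcations are handled natively by the pruning
algorithm; taxa missing from the state matrix contribute no information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .model import MitoError

MISSING = {None, "", "?", "-", "NA"}


def transition_matrix(k: int, rate: float, t: float) -> np.ndarray:
    """Equal-rates Mk transition probabilities for a branch of length t."""
    if rate <= 0:
        raise MitoError("rate must be positive")
    if t < 0:
        raise MitoError("negative branch length")
    e = math.exp(-k * rate * t / (k - 1))
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (1.0 - 1.0 / k) * e)
    return P


@dataclass
class CharacterStateMatrix:
    """Taxon -> state-letter assignments over a fixed alphabet."""

    states: dict[str, str | None]
    alphabet: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        observed = sorted(
            {s for s in self.states.values() if s not in MISSING}
        )
        if not self.alphabet:
            self.alphabet = tuple(observed)
        unknown = [s for s in observed if s not in self.alphabet]
        if unknown:
            raise MitoError(f"states {unknown} outside alphabet {self.alphabet}")
        if len(self.alphabet) < 2:
            raise MitoError("Mk model needs an alphabet of k >= 2 states")

    @classmethod
    def from_tsv(cls, path: str, alphabet: tuple[str, ...] = ()) -> "CharacterStateMatrix":
        states: dict[str, str | None] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("taxon", "taxa", "species"):
                    continue
                taxon = parts[0]
                state = parts[1] if len(parts) > 1 and parts[1] not in MISSING else None
                states[taxon] = state
        return cls(states, alphabet)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tstate\n")
            for t, s in self.states.items():
                fh.write(f"{t}\t{s if s is not None else '?'}\n")


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        t = tree
    elif isinstance(tree, str) and ("(" in tree):
        t = dendropy.Tree.get(data=tree, schema="newick")
    else:
        t = dendropy.Tree.get(path=str(tree), schema="newick")
    labels = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise MitoError("leaf labels are not unique")
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise MitoError(f"negative branch length {edge.length}")
    return t


def label_nodes(tree: dendropy.Tree) -> dict[int, str]:
    """Stable node labels: the taxon label at tips, existing internal labels
    where present, otherwise N<i> in preorder."""
    labels: dict[int, str] = {}
    i = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            labels[id(nd)] = nd.taxon.label
        else:
            labels[id(nd)] = nd.label or f"N{i}"
            i += 1
    return labels


class MkModel:
    """Equal-rates Mk model of one discrete character on a rooted tree.

    Parameters
    ----------
    tree : dendropy.Tree | str
        Rooted tree with branch lengths (newick string, path, or tree object).
    states : CharacterStateMatrix | dict
        Tip state assignments; taxa absent or marked '?' contribute all-ones
        partials (no information).
    alphabet : tuple of str, optional
        State alphabet; defaults to the observed states.
    """

    def __init__(self, tree, states, alphabet: tuple[str, ...] = ()):
        self.tree = _load_tree(tree)
        if isinstance(states, dict):
            states = CharacterStateMatrix(dict(states), alphabet)
        elif alphabet and not states.alphabet:
            states = CharacterStateMatrix(states.states, alphabet)
        self.data = states
        self.k = len(self.data.alphabet)
        self._index = {s: i for i, s in enumerate(self.data.alphabet)}
        self.node_labels = label_nodes(self.tree)
        self.root_label = self.node_labels[id(self.tree.seed_node)]
        self._leaf_partials: dict[int, np.ndarray] = {}
        for lf in self.tree.leaf_node_iter():
            s = self.data.states.get(lf.taxon.label)
            if s in MISSING:
                part = np.ones(self.k)
            else:
                part = np.zeros(self.k)
                part[self._index[s]] = 1.0
            self._leaf_partials[id(lf)] = part

    # -- likelihood ---------------------------------------------------------

    def _upward(self, rate: float):
        """Post-order pruning partials with per-node log scaling."""
        up: dict[int, np.ndarray] = {}
        logscale = 0.0
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                up[id(nd)] = self._leaf_partials[id(nd)].copy()
                continue
            part = np.ones(self.k)
            for ch in nd.child_nodes():
                t = ch.edge.length or 0.0
                P = transition_matrix(self.k, rate, t)
                part *= P @ up[id(ch)]
            mx = part.max()
            if mx <= 0:
                return up, -np.inf
            part /= mx
            logscale += math.log(mx)
            up[id(nd)] = part
        return up, logscale

    def loglike(self, rate: float) -> float:
        """Pruning log-likelihood under a uniform root prior."""
        up, logscale = self._upward(rate)
        if logscale == -np.inf:
            return -np.inf
        root = up[id(self.tree.seed_node)]
        lik = float(np.mean(root))  # uniform prior 1/k
        return math.log(lik) + logscale

    def fit(self, method: str = "ml", mcmc_samples: int = 2000,
            mcmc_burn: int = 500, seed: int | None = None) -> "MkResults":
        """Estimate the substitution rate and reconstruct ancestral states.

        ``method='ml'`` (default) maximizes the likelihood by golden-section
        search on log-rate over [1e-6, 1e3]; ``method='mcmc'`` additionally
        averages the marginal reconstruction over a Metropolis posterior
        sample of the rate (uniform prior), for BBM-style occurrences.
        """
        observed = {s for s in self.data.states.values() if s not in MISSING}
        invariant = len(observed) <= 1
        lo, hi = math.log(1e-6), math.log(1e3)
        x, _ = _golden_max(lambda x: self.loglike(math.exp(x)), lo, hi, tol=1e-6)
        rate = math.exp(x)
        flags = []
        if invariant:
            flags.append("invariant character: rate estimate is a lower bound")
        elif x - lo < 1e-3:
            flags.append("rate at search lower bound")
        llf = self.loglike(rate)
        marginals = self._marginals(rate)
        if method == "mcmc":
            marginals, rate_samples = self._mcmc_marginals(
                rate, mcmc_samples, mcmc_burn, seed
            )
            flags.append(f"posterior-averaged over {len(rate_samples)} rate samples")
        return MkResults(self, rate, llf, marginals, flags)

    # -- marginal reconstruction --------------------------------------------

    def _marginals(self, rate: float) -> pd.DataFrame:
        up, _ = self._upward(rate)
        down: dict[int, np.ndarray] = {
            id(self.tree.seed_node): np.full(self.k, 1.0 / self.k)
        }
        # cache the child messages used in the upward pass
        msg: dict[int, np.ndarray] = {}
        for nd in self.tree.postorder_node_iter():
            if nd.parent_node is not None:
                t = nd.edge.length or 0.0
                P = transition_matrix(self.k, rate, t)
                msg[id(nd)] = P @ up[id(nd)]
        rows = {}
        for nd in self.tree.preorder_node_iter():
            d = down[id(nd)]
            for ch in nd.child_nodes():
                sib = d.copy()
                for other in nd.child_nodes():
                    if other is not ch:
                        sib *= msg[id(other)]
                t = ch.edge.length or 0.0
                P = transition_matrix(self.k, rate, t)
                dn = P.T @ sib
                mx = dn.max()
                down[id(ch)] = dn / mx if mx > 0 else dn
            post = d * up[id(nd)]
            total = post.sum()
            rows[self.node_labels[id(nd)]] = (
                post / total if total > 0 else np.full(self.k, 1.0 / self.k)
            )
        df = pd.DataFrame.from_dict(rows, orient="index", columns=self.data.alphabet)
        df.index.name = "node"
        return df

    def _mcmc_marginals(self, start_rate: float, n: int, burn: int,
                        seed: int | None):
        rng = np.random.default_rng(seed)
        x = math.log(start_rate)
        lo, hi = math.log(1e-6), math.log(1e3)
        lp = self.loglike(math.exp(x)) + x  # Jacobian for uniform-rate prior
        samples = []
        acc = pd.DataFrame(0.0, index=self._marginals(start_rate).index,
                           columns=self.data.alphabet)
        kept = 0
        for it in range(n):
            xp = x + rng.normal(0, 0.3)
            if not (lo <= xp <= hi):
                continue
            lpp = self.loglike(math.exp(xp)) + xp
            if math.log(rng.uniform()) < lpp - lp:
                x, lp = xp, lpp
            if it >= burn and it % 10 == 0:
                acc += self._marginals(math.exp(x))
                samples.append(math.exp(x))
                kept += 1
        if kept == 0:  # degenerate chain; fall back to the ML point
            return self._marginals(start_rate), [start_rate]
        return acc / kept, samples


def _golden_max(f, a: float, b: float, tol: float = 1e-6):
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


@dataclass
class MkResults:
    """Fitted Mk reconstruction: rate, log-likelihood, per-node marginals."""

    model: MkModel
    rate: float
    llf: float
    marginals: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    @property
    def occurrence(self) -> pd.DataFrame:
        """Marginal probabilities as percentages."""
        return self.marginals * 100.0

    def map_states(self) -> dict[str, str]:
        """Maximum-probability state per node (ties broken by alphabet order)."""
        return {node: row.idxmax() for node, row in self.marginals.iterrows()}

    def count_transitions(self) -> dict[tuple[str, str], int]:
        """Parsimony-style census of branches whose maximum-probability state
        changes, per (parent state, child state) pair."""
        states = self.map_states()
        labels = self.model.node_labels
        events: dict[tuple[str, str], int] = {}
        for nd in self.model.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            a = states[labels[id(nd.parent_node)]]
            b = states[labels[id(nd)]]
            if a != b:
                events[(a, b)] = events.get((a, b), 0) + 1
        return events

    def annotated_newick(self) -> str:
        """Newick with per-node comment [&state=X,p=...] annotations."""
        states = self.map_states()
        labels = self.model.node_labels
        for nd in self.model.tree.preorder_node_iter():
            lab = labels[id(nd)]
            p = self.marginals.loc[lab].max()
            nd.annotations.drop()
            nd.annotations.add_new("state", states[lab])
            nd.annotations.add_new("p", f"{p:.4f}")
        return self.model.tree.as_string(
            schema="newick", suppress_annotations=False
        ).strip()

    def to_tsv(self) -> str:
        df = self.occurrence.round(2)
        df.insert(0, "map_state", pd.Series(self.map_states()))
        return df.to_csv(sep="\t")

    def summary(self) -> str:
        k = self.model.k
        n = len(self.model.tree.leaf_nodes())
        lines = [
            "Mk ancestral state reconstruction",
            "=" * 46,
            f"states (k):          {k} ({', '.join(self.model.data.alphabet)})",
            f"tips:                {n}",
            f"rate (ML):           {self.rate:.6g}",
            f"log-likelihood:      {self.llf:.4f}",
            f"root node:           {self.model.root_label}",
        ]
        root = self.occurrence.loc[self.model.root_label]
        lines.append("root occurrences (%): "
                     + ", ".join(f"{s}={v:.1f}" for s, v in root.items()))
        trans = self.count_transitions()
        if trans:
            lines.append("state changes (MAP): "
                         + ", ".join(f"{a}->{b}: {c}" for (a, b), c in sorted(trans.items())))
        for fl in self.flags:
            lines.append(f"note: {fl}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# spec-surface convenience functions
# --------------------------------------------------------------------------

def mk_likelihood(tree, states, rate: float, alphabet: tuple[str, ...] = ()) -> float:
    return MkModel(tree, states, alphabet).loglike(rate)


def estimate_rate(tree, states, alphabet: tuple[str, ...] = ()) -> tuple[float, list[str]]:
    res = MkModel(tree, states, alphabet).fit()
    return res.rate, res.flags


def marginal_ancestral(tree, states, rate: float,
                       alphabet: tuple[str, ...] = ()) -> pd.DataFrame:
    model = MkModel(tree, states, alphabet)
    return model._marginals(rate)


def count_transitions(tree, states, rate: float,
                      alphabet: tuple[str, ...] = ()) -> dict[tuple[str, str], int]:
    model = MkModel(tree, states, alphabet)
    res = MkResults(model, rate, model.loglike(rate), model._marginals(rate))
    return res.count_transitions()
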