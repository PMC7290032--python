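"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their parameters and a seed, so
every stage of the pipeline is testable without downloads:

* :func:`simulate_yule_tree` — ultrametric pure-birth species trees;
* :func:`simulate_trait_pair` — paired presence/absence traits evolved
  by the loss-only CTMC from a both-present root (the forward
  counterpart of the co-occurrence models);
* :func:`simulate_branch_rates` — per-gene branch lengths with a
  tunable between-gene rate correlation (the structure ERC detects);
* :func:`simulate_spectral_counts` — bait/control spectral-count tables
  with negative-binomial background and fold-enriched true interactors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from phylocoev.cooccurrence import LossGenerator
from phylocoev.phylo_io import BranchLengthTable, Phylogeny, TraitMatrix
from phylocoev.interactome import SpectralCountTable

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_trait_pair",
    "simulate_branch_rates",
    "simulate_spectral_counts",
]


@dataclass
class SimulationConfig:
    """Bundle of generator settings; identical config + seed gives
    bit-identical outputs."""

    seed: int = 0
    tree: dict = field(default_factory=lambda: {"n_tips": 40, "birth_rate": 1.0})
    traits: dict = field(
        default_factory=lambda: {
            "model": "independent",
            "rates": {"beta1": 0.3, "beta2": 0.3},
        }
    )
    erc: dict = field(
        default_factory=lambda: {
            "n_branches": 30,
            "n_genes": 60,
            "correlated_block": 10,
            "rho": 0.5,
            "rate_noise_sd": 0.3,
        }
    )
    spectra: dict = field(
        default_factory=lambda: {
            "n_proteins": 200,
            "n_true_interactors": 20,
            "fold_change": 10.0,
            "background_mean": 20.0,
            "background_dispersion": 0.5,
            "n_replicates": 2,
        }
    )


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Ultrametric pure-birth tree with ``n_tips`` labeled tips.

    Lineages split at rate ``birth_rate`` each; starting from the crown
    (2 lineages), the process runs until ``n_tips`` lineages exist and
    then for one further exponential waiting time at the full rate, so
    the expected depth is sum_{k=2..n} 1/(birth_rate * k).  Tips are
    labeled ``t1..tn``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.edge.length = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [c1, c2]
    birth_times = {id(c1): 0.0, id(c2): 0.0}
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(0, k)
        parent = active.pop(i)
        parent.edge.length = t - birth_times[id(parent)]
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        birth_times[id(a)] = birth_times[id(b)] = t
        active.extend([a, b])
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for j, leaf in enumerate(active):
        leaf.edge.length = t - birth_times[id(leaf)]
    # stable tip labels in left-to-right order
    leaves = [nd for nd in tree.leaf_node_iter()]
    for j, leaf in enumerate(leaves, start=1):
        tax = taxa.new_taxon(label=f"t{j}")
        leaf.taxon = tax
    return Phylogeny(tree)


def _gillespie_branch(state: int, Q: np.ndarray, t: float, rng: np.random.Generator) -> int:
    """Evolve one lineage for time ``t`` by exponential waiting times."""
    remaining = t
    k = Q.shape[0]
    while True:
        total = -Q[state, state]
        if total <= 0:
            return state
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return state
        remaining -= wait
        probs = Q[state].clip(min=0.0)
        probs = probs / probs.sum()
        state = int(rng.choice(k, p=probs))


def simulate_trait_pair(phy: Phylogeny, gen: LossGenerator, seed: int = 0,
                        gene_names: tuple[str, str] = ("gene1", "gene2")) -> TraitMatrix:
    """Simulate tip presence/absence for two genes under a loss generator.

    The root starts both-present (present, for a single-trait
    generator) and states evolve down every branch by sampling
    exponential waiting times for the allowed loss transitions.  For a
    single-trait generator the same loss process is run independently
    for both genes.
    """
    rng = np.random.default_rng(seed)
    Q = gen.Q()

    def run(Qm: np.ndarray) -> dict[str, int]:
        states: dict[int, int] = {}
        out: dict[str, int] = {}
        for nd in phy.tree.preorder_node_iter():
            if nd.parent_node is None:
                states[id(nd)] = 0  # fixed root: present / both-present
                continue
            t = nd.edge.length or 0.0
            states[id(nd)] = _gillespie_branch(states[id(nd.parent_node)], Qm, t, rng)
            if nd.is_leaf():
                out[nd.taxon.label] = states[id(nd)]
        return out

    if gen.kind == "independent-single":
        tips1 = run(Q)
        tips2 = run(Q)
        df = pd.DataFrame(
            {
                gene_names[0]: {sp: 1.0 - s for sp, s in tips1.items()},
                gene_names[1]: {sp: 1.0 - s for sp, s in tips2.items()},
            }
        )
    else:
        from phylocoev.cooccurrence import PAIR_STATES

        tips = run(Q)
        df = pd.DataFrame(
            {
                gene_names[0]: {sp: float(PAIR_STATES[s][0]) for sp, s in tips.items()},
                gene_names[1]: {sp: float(PAIR_STATES[s][1]) for sp, s in tips.items()},
            }
        )
    df = df.loc[sorted(df.index, key=lambda x: (len(x), x))]
    df.index.name = "species"
    return TraitMatrix(df)


def simulate_independent_traits(
    phy: Phylogeny, beta1: float, beta2: float, seed: int = 0,
    gene_names: tuple[str, str] = ("gene1", "gene2"),
) -> TraitMatrix:
    """Two genes lost independently at rates beta1, beta2 (null of the LRT)."""
    rng = np.random.default_rng(seed)
    cols = {}
    for name, beta in zip(gene_names, (beta1, beta2)):
        Q = LossGenerator.single(beta).Q()
        states: dict[int, int] = {}
        col: dict[str, float] = {}
        for nd in phy.tree.preorder_node_iter():
            if nd.parent_node is None:
                states[id(nd)] = 0
                continue
            t = nd.edge.length or 0.0
            states[id(nd)] = _gillespie_branch(states[id(nd.parent_node)], Q, t, rng)
            if nd.is_leaf():
                col[nd.taxon.label] = 1.0 - states[id(nd)]
        cols[name] = col
    df = pd.DataFrame(cols)
    df = df.loc[sorted(df.index, key=lambda x: (len(x), x))]
    df.index.name = "species"
    return TraitMatrix(df)


def simulate_branch_rates(
    n_branches: int,
    genes,
    correlated_block,
    rho: float,
    seed: int = 0,
    rate_noise_sd: float = 0.3,
    reference_scale: float = 1.0,
) -> BranchLengthTable:
    """Per-gene branch lengths with a tunable within-block rate correlation.

    Each branch carries a shared latent factor; genes in the correlated
    block load on it with weight sqrt(rho) so each within-block pair of
    latent rate deviations has correlation ``rho``, while other genes
    are independent.  Gene branch lengths are the positive reference
    lengths times log-normal rate multipliers
    exp(rate_noise_sd * deviation); for moderate ``rate_noise_sd`` the
    Pearson correlation of the multipliers stays close to ``rho``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if n_branches < 3:
        raise ValueError("need at least 3 branches")
    genes = list(genes)
    block = set(correlated_block)
    unknown = block - set(genes)
    if unknown:
        raise ValueError(f"correlated_block genes not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    reference = reference_scale * rng.lognormal(mean=0.0, sigma=0.5, size=n_branches)
    z = rng.standard_normal(n_branches)  # shared per-branch factor
    cols = {}
    s = np.sign(rho) * np.sqrt(abs(rho))
    resid = np.sqrt(1.0 - abs(rho))
    for g in genes:
        eps = rng.standard_normal(n_branches)
        x = s * z + resid * eps if g in block else eps
        cols[g] = reference * np.exp(rate_noise_sd * x)
    branch_ids = [f"b{i}" for i in range(n_branches)]
    return BranchLengthTable(
        branch_ids=branch_ids,
        reference=reference,
        gene_lengths=pd.DataFrame(cols, index=branch_ids),
    )


def simulate_spectral_counts(
    n_proteins: int = 200,
    n_true_interactors: int = 20,
    fold_change: float = 10.0,
    background_mean: float = 20.0,
    background_dispersion: float = 0.5,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[SpectralCountTable, pd.Series]:
    """Bait/control spectral-count table with planted true interactors.

    Control counts per protein and replicate are negative binomial
    around a log-normal per-protein baseline with dispersion ``alpha``
    (variance mu + alpha mu^2; spectral counting is overdispersed).
    Bait counts use the same baseline scaled by ``fold_change`` for the
    first ``n_true_interactors`` proteins.  Unique peptides grow with
    counts and are capped by them.  Returns the table and a boolean
    truth series for benchmarking the enrichment filter.
    """
    if fold_change <= 1 and n_true_interactors > 0:
        raise ValueError("fold_change must be > 1 for true interactors")
    if n_true_interactors > n_proteins:
        raise ValueError("more true interactors than proteins")
    rng = np.random.default_rng(seed)

    accession = [f"P{i:05d}" for i in range(n_proteins)]
    genes = pd.Series([f"GENE{i}" for i in range(n_proteins)], index=accession)
    truth = pd.Series(
        [i < n_true_interactors for i in range(n_proteins)], index=accession
    )

    baseline = rng.lognormal(mean=np.log(background_mean), sigma=0.6, size=n_proteins)
    alpha = background_dispersion

    def nb(mu: np.ndarray) -> np.ndarray:
        if alpha <= 0:
            return rng.poisson(mu)
        r = 1.0 / alpha
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    counts = {}
    peptides = {}
    roles = {}
    bait_mu = baseline * np.where(truth.to_numpy(), fold_change, 1.0)
    for rep in range(1, n_replicates + 1):
        for role, mu in (("bait", bait_mu), ("control", baseline)):
            name = f"{role}_rep{rep}"
            c = nb(mu)
            counts[name] = c
            with np.errstate(divide="ignore"):
                pep = np.where(c > 0, 1 + rng.poisson(np.sqrt(c)), 0)
            peptides[name] = np.minimum(pep, c)
            roles[name] = role
    table = SpectralCountTable(
        gene_symbols=genes,
        peptides=pd.DataFrame(peptides, index=accession),
        counts=pd.DataFrame(counts, index=accession),
        roles=roles,
    )
    return table, truth
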