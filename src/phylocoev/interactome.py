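"""Spectral-count enrichment filters for BioID / co-IP interactomes.

Proximity labeling (BioID) and co-immunoprecipitation followed by mass
spectrometry yield, per protein accession, unique-peptide counts and
total spectral counts in bait and control pulldowns.  Putative
interactors are called by simple, auditable rules:

* a unique-peptide floor (evidence the protein was really identified),
  applied either in any bait replicate or in each replicate;
* a fold-enrichment threshold of the bait count statistic (total or
  replicate-average spectral counts) over the matched control, with
  "at least k-fold" read inclusively;
* proteins absent from the control but seen in the bait pass the fold
  test as infinitely enriched (flagged), since genuine interactors are
  often undetectable in control pulldowns — a pseudocount alternative
  is available;
* naturally biotinylated carboxylases are excluded from BioID runs
  (they bind streptavidin regardless of proximity);
* multiple enriched isoforms of one protein collapse to a single
  gene-level hit.

Experiments are combined by gene-level intersection with full Venn
region counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCountTable",
    "InteractorSet",
    "DEFAULT_CARBOXYLASES",
    "enrichment_filter",
    "intersect_experiments",
    "read_spectral_counts",
]

# Streptavidin-binding endogenous carboxylases routinely removed from
# BioID hit lists; the class, not a fixed list, is the rule — edit as needed.
DEFAULT_CARBOXYLASES: tuple[str, ...] = (
    "PC", "PCCA", "PCCB", "MCCC1", "MCCC2", "ACACA", "ACACB",
)


@dataclass
class SpectralCountTable:
    """Per-accession peptide and spectral counts across samples.

    ``peptides`` and ``counts`` are accession x sample integer frames;
    ``roles`` maps each sample (one technical replicate each) to
    ``"bait"`` or ``"control"``; ``gene_symbols`` maps accession to the
    gene-level identifier used for isoform collapsing.
    """

    gene_symbols: pd.Series  # index: accession
    peptides: pd.DataFrame  # index: accession, columns: samples
    counts: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for name, df in (("peptides", self.peptides), ("counts", self.counts)):
            arr = df.to_numpy()
            if (arr < 0).any():
                raise ValueError(f"negative values in {name}")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name} must be integer counts")
        bad = {r for r in self.roles.values()} - {"bait", "control"}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if "bait" not in self.roles.values() or "control" not in self.roles.values():
            raise ValueError("need at least one bait and one control sample")
        for df in (self.peptides, self.counts):
            missing = set(df.columns) - set(self.roles)
            if missing:
                raise ValueError(f"samples without a role: {sorted(missing)}")

    def samples(self, role: str) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == role]

    @property
    def accessions(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class InteractorSet:
    """Gene-level interactor calls for one experiment."""

    experiment_id: str
    genes: set[str]
    evidence: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.evidence.index.duplicated().any():
            raise ValueError("duplicate gene-level entries in evidence table")


def _bait_control_stats(table: SpectralCountTable, count_rule: str):
    bait = table.samples("bait")
    ctrl = table.samples("control")
    if count_rule == "total":
        bstat = table.counts[bait].sum(axis=1).astype(float)
        cstat = table.counts[ctrl].sum(axis=1).astype(float)
    elif count_rule == "replicate-average":
        bstat = table.counts[bait].mean(axis=1)
        cstat = table.counts[ctrl].mean(axis=1)
    else:
        raise ValueError(f"unknown count_rule {count_rule!r}")
    return bstat, cstat


def enrichment_filter(
    table: SpectralCountTable,
    min_unique_peptides: int = 2,
    min_fold: float = 3.0,
    peptide_rule: str = "any-replicate",
    count_rule: str = "total",
    exclusions=DEFAULT_CARBOXYLASES,
    control_zero: str = "infinite",
    pseudocount: float = 0.5,
    experiment_id: str = "experiment",
) -> InteractorSet:
    """Call enriched interactors from a spectral-count table.

    A row passes when (a) its bait unique-peptide counts satisfy
    ``peptide_rule`` at the ``min_unique_peptides`` floor, and (b) its
    bait count statistic is at least ``min_fold`` times the control
    statistic (inclusive).  With ``control_zero="infinite"`` (default),
    a zero-control, positive-bait row passes with infinite enrichment
    and is flagged; ``control_zero="pseudocount"`` instead adds
    ``pseudocount`` to both statistics.  Exclusion-list genes are
    removed, and accessions collapse to gene symbols: a gene passes if
    at least one isoform passes, reporting its best isoform's evidence.
    """
    if min_unique_peptides < 1:
        raise ValueError("min_unique_peptides must be >= 1")
    if min_fold <= 0:
        raise ValueError("min_fold must be > 0")
    if peptide_rule not in ("any-replicate", "each-replicate"):
        raise ValueError(f"unknown peptide_rule {peptide_rule!r}")
    if control_zero not in ("infinite", "pseudocount"):
        raise ValueError(f"unknown control_zero {control_zero!r}")
    if len(table.accessions) == 0:
        warnings.warn("empty spectral-count table; no interactors", UserWarning,
                      stacklevel=2)
        return InteractorSet(experiment_id, set(), pd.DataFrame())

    bait = table.samples("bait")
    pep = table.peptides[bait]
    if peptide_rule == "any-replicate":
        pep_ok = pep.max(axis=1) >= min_unique_peptides
    else:
        pep_ok = pep.min(axis=1) >= min_unique_peptides

    bstat, cstat = _bait_control_stats(table, count_rule)
    if control_zero == "pseudocount":
        fold = (bstat + pseudocount) / (cstat + pseudocount)
        fold_ok = fold >= min_fold
        infinite = pd.Series(False, index=bstat.index)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = bstat / cstat
        infinite = (cstat == 0) & (bstat > 0)
        fold = fold.where(~infinite, np.inf)
        fold_ok = infinite | (bstat >= min_fold * cstat) & (bstat > 0)

    excluded = table.gene_symbols.isin(set(exclusions or ()))
    keep = pep_ok & fold_ok & ~excluded

    ev = pd.DataFrame(
        {
            "gene": table.gene_symbols,
            "bait_peptides_max": pep.max(axis=1),
            "bait_peptides_min": pep.min(axis=1),
            "bait_stat": bstat,
            "control_stat": cstat,
            "fold_enrichment": fold,
            "infinite_enrichment": infinite,
        }
    )[keep]

    # isoform collapsing: keep each gene's best-supported accession
    ev = ev.sort_values(
        ["fold_enrichment", "bait_stat"], ascending=False, kind="stable"
    )
    ev = ev.reset_index(names="accession")
    n_isoforms = ev.groupby("gene")["accession"].transform("size")
    ev["n_enriched_isoforms"] = n_isoforms
    ev = ev.drop_duplicates(subset="gene", keep="first").set_index("gene").sort_index()

    return InteractorSet(
        experiment_id=experiment_id,
        genes=set(ev.index),
        evidence=ev,
    )


def intersect_experiments(sets: list[InteractorSet]):
    """Gene-level intersection and Venn region counts.

    Returns ``(common, regions)`` where ``common`` is the set of genes
    present in every experiment and ``regions`` maps each non-empty
    combination of experiment ids (a sorted tuple) to the number of
    genes found in exactly those experiments.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 interactor sets to intersect")
    ids = [s.experiment_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate experiment ids: {ids}")
    membership = {s.experiment_id: s.genes for s in sets}
    common = set.intersection(*(s.genes for s in sets))
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            inside = set.intersection(*(membership[i] for i in combo))
            outside = set.union(
                set(), *(membership[i] for i in ids if i not in combo)
            )
            regions[tuple(combo)] = len(inside - outside)
    return common, regions


def read_spectral_counts(table_source, config: dict) -> SpectralCountTable:
    """Build a :class:`SpectralCountTable` from a TSV plus a role config.

    ``config`` declares column roles::

        accession: Accession
        gene: Gene
        samples:
          bait_rep1:    {role: bait,    peptides: Pep_B1, counts: TSC_B1}
          control_rep1: {role: control, peptides: Pep_C1, counts: TSC_C1}
    """
    df = pd.read_csv(table_source, sep="\t")
    acc_col = config["accession"]
    gene_col = config["gene"]
    if df[acc_col].duplicated().any():
        dup = df[acc_col][df[acc_col].duplicated()].tolist()
        raise ValueError(f"duplicate accessions: {dup[:5]}")
    df = df.set_index(acc_col)
    samples = config["samples"]
    pep = pd.DataFrame(
        {name: df[spec["peptides"]] for name, spec in samples.items()}
    ).astype(int)
    cnt = pd.DataFrame(
        {name: df[spec["counts"]] for name, spec in samples.items()}
    ).astype(int)
    roles = {name: spec["role"] for name, spec in samples.items()}
    return SpectralCountTable(
        gene_symbols=df[gene_col].astype(str),
        peptides=pep,
        counts=cnt,
        roles=roles,
    )
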