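"""Protein- and residue-level network features for missense mutations.

A mutation is characterised by 16 network features:

* 7 protein-level features — the centralities of the mutated protein in the
  intact network (degree, betweenness, closeness, eigenvector, clustering
  coefficient, load, PageRank).  They describe how important the protein is
  to the network and are shared by all mutations in the protein.
* 9 residue-level features — the 3D location of the mutated residue (core 0,
  surface 1, interface 2) plus the change (original minus perturbed) of each
  of the seven centralities and the percent degree change, after deleting
  the network edges the mutation can disrupt.

The edgetic perturbation model: a core mutation destabilises the protein
and severs all of its interactions; an interface mutation severs exactly
the interactions whose interface contains the mutated position; a surface
non-interface mutation severs nothing, so all its change features are 0.
Gain of new interactions is not modelled.  Nodes are never deleted — only
edges — so network size (and therefore centrality normalisation) is
identical before and after perturbation.

Mutations at residues with no structural annotation, or in the ambiguous
RSA band, cannot be scored and are skipped (reported via the coverage
fraction of :func:`featurize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .centrality import (
    PROTEIN_FEATURE_NAMES,
    CsrGraph,
    ProteinFeatures,
)
from .interactome import ResidueLocation, StructurallyResolvedNetwork, _edge_key

logger = logging.getLogger(__name__)

__all__ = [
    "Mutation",
    "ResidueFeatures",
    "NotScoreableError",
    "NetworkFeaturizer",
    "protein_centralities",
    "affected_edges",
    "perturb_and_diff",
    "featurize",
    "read_mutation_table",
    "read_aa_table",
    "RESIDUE_FEATURE_NAMES",
    "NETWORK_FEATURE_NAMES",
]

RESIDUE_FEATURE_NAMES = (
    "location_3d",
    "degree_change",
    "betweenness_change",
    "closeness_change",
    "eigenvector_change",
    "clustering_change",
    "load_change",
    "pagerank_change",
    "percent_degree_change",
)

#: Column order of the 16-feature network block (7 protein + 9 residue).
NETWORK_FEATURE_NAMES = PROTEIN_FEATURE_NAMES + RESIDUE_FEATURE_NAMES

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class NotScoreableError(ValueError):
    """The mutation cannot be mapped to the network (unknown protein,
    unannotated position, or ambiguous RSA band)."""


@dataclass(frozen=True)
class Mutation:
    """A missense mutation at a 1-based position of a canonical protein.

    ``label`` is 1 for the positive class (driver / pathogenic), 0 for the
    negative class (passenger / neutral), None when unknown.  ``gene``
    defaults to the protein identifier; it drives training-set balancing
    and gene-holdout fold assignment.
    """

    protein: str
    position: int
    ref_aa: str | None = None
    alt_aa: str | None = None
    gene: str | None = None
    label: int | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if (
            self.ref_aa is not None
            and self.alt_aa is not None
            and self.ref_aa == self.alt_aa
        ):
            raise ValueError(
                f"synonymous change {self.ref_aa}->{self.alt_aa} is not a "
                "missense mutation"
            )

    @property
    def gene_id(self) -> str:
        return self.gene if self.gene is not None else self.protein

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein, self.position, self.ref_aa or "", self.alt_aa or "")


class ResidueFeatures(NamedTuple):
    """The nine residue-level network features of one mutation."""

    location_3d: int
    degree_change: float
    betweenness_change: float
    closeness_change: float
    eigenvector_change: float
    clustering_change: float
    load_change: float
    pagerank_change: float
    percent_degree_change: float


@dataclass
class FeaturizeResult:
    """Feature matrix plus bookkeeping from :func:`featurize`."""

    table: pd.DataFrame
    coverage: float  # scoreable / total (NaN when no mutations were given)
    skipped: list[Mutation] = field(default_factory=list)


class NetworkFeaturizer:
    """Computes and caches network features against one network.

    The intact-network centralities are computed once; perturbed
    recomputations are cached by (protein, removed-edge set) so repeated
    mutations at the same interface, and all core mutations of one protein,
    share a single perturbation.
    """

    def __init__(self, net: StructurallyResolvedNetwork):
        self.net = net
        self.nodes = sorted(net.graph.nodes)
        self.index = {node: i for i, node in enumerate(self.nodes)}
        self.csr = CsrGraph.from_graph(net.graph, self.nodes)
        self._perturbed_cache: dict[tuple, ResidueFeatures] = {}

    # -- protein level --------------------------------------------------

    def protein_features(self, protein: str) -> ProteinFeatures:
        if protein not in self.index:
            raise KeyError(f"protein {protein!r} is not a node of the network")
        return self.csr.node_features(self.index[protein])

    # -- residue level --------------------------------------------------

    def location(self, mut: Mutation) -> ResidueLocation:
        loc = self.net.location(mut.protein, mut.position)
        if mut.protein not in self.index:
            raise NotScoreableError(
                f"{mut.protein} is not in the network; cannot score {mut.key}"
            )
        if loc is None:
            raise NotScoreableError(
                f"residue {mut.protein}:{mut.position} has no structural "
                "annotation"
            )
        if loc is ResidueLocation.UNRESOLVED:
            raise NotScoreableError(
                f"residue {mut.protein}:{mut.position} is in the ambiguous "
                "RSA band"
            )
        return loc

    def affected_edges(self, mut: Mutation) -> frozenset[tuple[str, str]]:
        """Edges deleted by the mutation under the edgetic model."""
        loc = self.location(mut)
        p = mut.protein
        if loc is ResidueLocation.SURFACE:
            return frozenset()
        incident = [_edge_key(p, nbr) for nbr in self.net.graph.neighbors(p)]
        if loc is ResidueLocation.CORE:
            return frozenset(incident)
        # interface: edges whose interface set on this protein holds the position
        return frozenset(
            key
            for key in incident
            if mut.position in self.net.interface_map[key][p]
        )

    def residue_features(self, mut: Mutation) -> ResidueFeatures:
        loc = self.location(mut)
        removed = self.affected_edges(mut)
        if not removed:  # surface (or interface of an untouched position set)
            return ResidueFeatures(int(loc), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        cache_key = (mut.protein, removed)
        cached = self._perturbed_cache.get(cache_key)
        if cached is not None:
            return ResidueFeatures(int(loc), *cached[1:])

        i = self.index[mut.protein]
        before = self.csr.node_features(i)
        edge_idx = [(self.index[a], self.index[b]) for a, b in removed]
        perturbed = self.csr.without_edges(edge_idx)
        after = perturbed.node_features(i)

        deg0 = before.degree
        pct = 100.0 * (deg0 - after.degree) / deg0 if deg0 > 0 else 0.0
        feats = ResidueFeatures(
            location_3d=int(loc),
            degree_change=float(before.degree - after.degree),
            betweenness_change=before.betweenness - after.betweenness,
            closeness_change=before.closeness - after.closeness,
            eigenvector_change=before.eigenvector - after.eigenvector,
            clustering_change=before.clustering_coefficient
            - after.clustering_coefficient,
            load_change=before.load - after.load,
            pagerank_change=before.pagerank - after.pagerank,
            percent_degree_change=pct,
        )
        self._perturbed_cache[cache_key] = feats
        return feats

    # -- assembly -------------------------------------------------------

    def featurize(
        self,
        mutations: Sequence[Mutation],
        aa_table: pd.DataFrame | None = None,
        *,
        network_only: bool | None = None,
    ) -> FeaturizeResult:
        """One feature row per scoreable mutation.

        With an amino-acid feature table (indexed by (protein, position,
        alt_aa)) the rows carry 16 network + the AA columns; mutations
        missing from the table are dropped.  In network-only mode
        (``aa_table is None``) rows carry the 16 network features only.
        """
        if network_only is None:
            network_only = aa_table is None
        rows: list[dict] = []
        index: list[tuple] = []
        skipped: list[Mutation] = []
        meta: list[dict] = []
        for mut in mutations:
            try:
                res = self.residue_features(mut)
            except NotScoreableError as exc:
                logger.info("skipping mutation %s: %s", mut.key, exc)
                skipped.append(mut)
                continue
            prot = self.protein_features(mut.protein)
            row = dict(zip(PROTEIN_FEATURE_NAMES, prot))
            row.update(zip(RESIDUE_FEATURE_NAMES, res))
            if not network_only:
                assert aa_table is not None
                aa_key = (mut.protein, mut.position, mut.alt_aa or "")
                if aa_key not in aa_table.index:
                    logger.info("no amino-acid features for %s; dropped", mut.key)
                    skipped.append(mut)
                    continue
                row.update(aa_table.loc[aa_key].to_dict())
            rows.append(row)
            index.append(mut.key)
            meta.append({"gene": mut.gene_id, "label": mut.label})
        n_total = len(mutations)
        coverage = float("nan") if n_total == 0 else len(rows) / n_total
        columns = list(NETWORK_FEATURE_NAMES)
        if not network_only and aa_table is not None:
            columns += list(aa_table.columns)
        table = pd.DataFrame(rows, columns=columns)
        if index:
            table.index = pd.MultiIndex.from_tuples(
                index, names=["protein", "position", "ref_aa", "alt_aa"]
            )
            meta_df = pd.DataFrame(meta, index=table.index)
            table.attrs["genes"] = meta_df["gene"]
            table.attrs["labels"] = meta_df["label"]
        return FeaturizeResult(table=table, coverage=coverage, skipped=skipped)


# ---------------------------------------------------------------------------
# Module-level convenience wrappers
# ---------------------------------------------------------------------------


def protein_centralities(
    net: StructurallyResolvedNetwork, protein: str
) -> ProteinFeatures:
    """Seven protein-level centralities of ``protein`` in the intact network."""
    return NetworkFeaturizer(net).protein_features(protein)


def affected_edges(
    net: StructurallyResolvedNetwork, mut: Mutation
) -> frozenset[tuple[str, str]]:
    """Edges the mutation removes under the edgetic perturbation model."""
    return NetworkFeaturizer(net).affected_edges(mut)


def perturb_and_diff(
    net: StructurallyResolvedNetwork, mut: Mutation
) -> ResidueFeatures:
    """Residue-level features: original minus perturbed centralities."""
    return NetworkFeaturizer(net).residue_features(mut)


def featurize(
    net: StructurallyResolvedNetwork,
    mutations: Sequence[Mutation],
    aa_table: pd.DataFrame | None = None,
    *,
    network_only: bool | None = None,
) -> FeaturizeResult:
    """Feature matrix for a list of mutations (see
    :meth:`NetworkFeaturizer.featurize`)."""
    return NetworkFeaturizer(net).featurize(
        mutations, aa_table, network_only=network_only
    )


# ---------------------------------------------------------------------------
# Tabular input
# ---------------------------------------------------------------------------


def read_mutation_table(path: str | Path) -> list[Mutation]:
    """Read mutations from TSV.

    Two dialects are accepted: the native header ``gene  protein  position
    ref_aa  alt_aa  label`` (gene/ref/alt/label optional), or a MAF-lite
    header with ``Hugo_Symbol``, ``Protein_position`` and ``Amino_acids``
    (slash-separated ref/alt) columns plus a protein column.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {str(c).strip().lower(): c for c in df.columns}

    def get(row, *names):
        for name in names:
            col = cols.get(name)
            if col is not None:
                val = row[col]
                if pd.notna(val):
                    return val
        return None

    if "hugo_symbol" in cols and "protein_position" in cols:
        muts = []
        for _, row in df.iterrows():
            aas = get(row, "amino_acids")
            ref, alt = (str(aas).split("/") + [None])[:2] if aas else (None, None)
            muts.append(
                Mutation(
                    protein=str(get(row, "protein", "uniprot", "swissprot_acc_id")),
                    position=int(get(row, "protein_position")),
                    ref_aa=ref,
                    alt_aa=alt,
                    gene=str(get(row, "hugo_symbol")),
                    label=_parse_label(get(row, "label")),
                )
            )
        return muts

    if "protein" not in cols or "position" not in cols:
        raise ValueError(
            f"mutation table {path} needs 'protein' and 'position' columns "
            f"(or MAF-lite Hugo_Symbol/Protein_position); found {list(df.columns)!r}"
        )
    muts = []
    for _, row in df.iterrows():
        gene = get(row, "gene")
        muts.append(
            Mutation(
                protein=str(row[cols["protein"]]),
                position=int(row[cols["position"]]),
                ref_aa=_opt_str(get(row, "ref_aa")),
                alt_aa=_opt_str(get(row, "alt_aa")),
                gene=None if gene is None else str(gene),
                label=_parse_label(get(row, "label")),
            )
        )
    return muts


def _opt_str(val) -> str | None:
    return None if val is None else str(val)


def _parse_label(val) -> int | None:
    if val is None:
        return None
    text = str(val).strip().lower()
    if text in {"1", "positive", "driver", "pathogenic", "true"}:
        return 1
    if text in {"0", "negative", "passenger", "neutral", "false"}:
        return 0
    if text in {"", "unknown", "na", "nan", "none"}:
        return None
    raise ValueError(f"unrecognised mutation label {val!r}")


def read_aa_table(path: str | Path) -> pd.DataFrame:
    """Read an amino-acid feature table (TSV) keyed by protein, position and
    alternate amino acid; remaining numeric columns are kept verbatim."""
    df = pd.read_csv(path, sep="\t")
    key_cols = ["protein", "position", "alt_aa"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise ValueError(f"AA feature table {path} lacks key columns {missing}")
    df["position"] = df["position"].astype(int)
    df["alt_aa"] = df["alt_aa"].astype(str)
    return df.set_index(key_cols)
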