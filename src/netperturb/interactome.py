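"""Structurally resolved protein–protein interaction networks.

A structurally resolved network is an undirected PPI graph in which every
interaction carries the specific interface residues (1-based UniProt
positions) on each partner, and every annotated residue of every protein is
classified by its 3D location: buried in the protein core, exposed on the
surface, or part of an interaction interface.

The pipeline is:

1. :func:`parse_interface_table` — read the three-column interface-residue
   table (``Uniprot1``, ``Uniprot2``, ``Uniprot1_residue``; one row per
   interface residue, TSV or XLSX).
2. :func:`filter_interactions` — drop interactions with fewer than five
   distinct interface residues on either partner.
3. :func:`build_network` — combine the retained interface annotations with
   per-chain relative solvent accessibility (RSA) to produce a
   :class:`StructurallyResolvedNetwork`.

Residues with RSA < 5% are core, > 15% surface; the ambiguous 5–15% band is
left unresolved and excluded from downstream analysis.  When a residue is
seen in several chains/structures, the strict-majority consensus over the
per-chain core/surface calls is used; ties stay unresolved.  Membership in
a retained interface always wins over the RSA-derived label.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueLocation",
    "InterfaceRecord",
    "ResidueRsaRecord",
    "StructurallyResolvedNetwork",
    "parse_interface_table",
    "read_rsa_table",
    "assign_rsa_location",
    "consensus_location",
    "filter_interactions",
    "build_network",
    "build_resolved_network",
    "InterfaceTableError",
]

#: RSA below this percentage designates a buried (core) residue.
CORE_RSA_THRESHOLD = 5.0
#: RSA above this percentage designates a solvent-exposed (surface) residue.
SURFACE_RSA_THRESHOLD = 15.0
#: Minimum distinct interface residues required on *each* partner.
MIN_INTERFACE_RESIDUES = 5

INTERFACE_COLUMNS = ("Uniprot1", "Uniprot2", "Uniprot1_residue")
RSA_COLUMNS = ("protein", "chain", "position", "rsa")


class InterfaceTableError(ValueError):
    """Malformed interface table (missing column or unparseable row)."""


class ResidueLocation(IntEnum):
    """3D location of a residue.

    Integer values double as the ordinal feature encoding used by the
    classifier (core 0, surface 1, interface 2).  ``UNRESOLVED`` marks the
    ambiguous RSA band and positions without structural annotation; such
    residues are excluded from analysis and are never encoded as a feature.
    """

    CORE = 0
    SURFACE = 1
    INTERFACE = 2
    UNRESOLVED = -1


class InterfaceRecord(NamedTuple):
    """One interface residue: ``residue_a`` sits on ``protein_a`` and
    contacts ``protein_b``."""

    protein_a: str
    protein_b: str
    residue_a: int


class ResidueRsaRecord(NamedTuple):
    """Relative solvent accessibility of one residue in one structure chain."""

    protein: str
    chain: str
    position: int
    rsa: float


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class StructurallyResolvedNetwork:
    """Undirected PPI graph with per-edge interface residues and per-residue
    3D locations.

    Attributes
    ----------
    graph:
        ``networkx.Graph`` over protein identifiers.
    interface_map:
        ``{(a, b): {a: frozenset(positions), b: frozenset(positions)}}`` with
        the edge key sorted lexicographically; use :meth:`interface_positions`
        for symmetric access.
    location_map:
        ``{protein: {position: ResidueLocation}}``.
    """

    graph: nx.Graph
    interface_map: dict[tuple[str, str], dict[str, frozenset[int]]]
    location_map: dict[str, dict[int, ResidueLocation]]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(_edge_key(a, b) for a, b in self.graph.edges)

    def n_interface_residues(self) -> int:
        """Total number of (edge, endpoint, position) interface annotations."""
        return sum(
            len(positions)
            for sides in self.interface_map.values()
            for positions in sides.values()
        )

    def interface_positions(self, a: str, b: str) -> dict[str, frozenset[int]]:
        """Interface residue sets of edge (a, b); order of a/b is irrelevant."""
        return self.interface_map[_edge_key(a, b)]

    def location(self, protein: str, position: int) -> ResidueLocation | None:
        """Location of a residue, or None when the residue is unannotated."""
        return self.location_map.get(protein, {}).get(position)

    # -- tabular export -------------------------------------------------

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b in self.edges:
            sides = self.interface_map[(a, b)]
            rows.append((a, b, len(sides[a]), len(sides[b])))
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "n_iface_a", "n_iface_b"]
        )

    def residue_table(self) -> pd.DataFrame:
        rows = [
            (protein, position, location.name)
            for protein in sorted(self.location_map)
            for position, location in sorted(self.location_map[protein].items())
        ]
        return pd.DataFrame(rows, columns=["protein", "position", "location"])

    def interface_table(self) -> pd.DataFrame:
        """Lossless interface-residue table in the three-column dialect."""
        rows = []
        for a, b in self.edges:
            sides = self.interface_map[(a, b)]
            for x, y in ((a, b), (b, a)):
                rows.extend((x, y, pos) for pos in sorted(sides[x]))
        return pd.DataFrame(rows, columns=list(INTERFACE_COLUMNS))

    def write_tables(self, edge_path: str | Path, residue_path: str | Path) -> None:
        self.edge_table().to_csv(edge_path, sep="\t", index=False)
        self.residue_table().to_csv(residue_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "tsv"
    if dialect == "xlsx":
        return pd.read_excel(path)
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t")
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'xlsx')")


def _resolve_columns(
    df: pd.DataFrame, wanted: Sequence[str], what: str
) -> list[str]:
    lower = {str(c).strip().lower(): c for c in df.columns}
    resolved = []
    for name in wanted:
        key = name.lower()
        if key not in lower:
            raise InterfaceTableError(
                f"{what} is missing required column {name!r}; "
                f"found columns {list(df.columns)!r}"
            )
        resolved.append(lower[key])
    return resolved


def parse_interface_table(
    path: str | Path, dialect: str | None = None
) -> list[InterfaceRecord]:
    """Parse an interface-residue table into records.

    The table must carry a header with columns ``Uniprot1``, ``Uniprot2``
    and ``Uniprot1_residue`` (matched case-insensitively); each row names
    one interface residue on the first protein.  Exact duplicate rows are
    dropped; row order is otherwise preserved.
    """
    df = _read_table(path, dialect)
    cols = _resolve_columns(df, INTERFACE_COLUMNS, f"interface table {path}")
    records: list[InterfaceRecord] = []
    seen: set[InterfaceRecord] = set()
    residues = df[cols[2]]
    for idx, (a, b, res) in enumerate(
        zip(df[cols[0]], df[cols[1]], residues)
    ):
        try:
            res_int = int(res)
            if res_int != float(res):
                raise ValueError
        except (TypeError, ValueError):
            raise InterfaceTableError(
                f"row {idx}: residue position {res!r} is not an integer"
            ) from None
        if res_int < 1:
            raise InterfaceTableError(
                f"row {idx}: residue position must be >= 1, got {res_int}"
            )
        rec = InterfaceRecord(str(a), str(b), res_int)
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    return records


def records_to_table(records: Iterable[InterfaceRecord]) -> pd.DataFrame:
    """Serialise records back to the three-column table (round-trippable)."""
    return pd.DataFrame(records, columns=list(INTERFACE_COLUMNS))


def read_rsa_table(path: str | Path) -> list[ResidueRsaRecord]:
    """Read a per-chain RSA table (TSV: protein, chain, position, rsa)."""
    df = pd.read_csv(path, sep="\t")
    cols = _resolve_columns(df, RSA_COLUMNS, f"RSA table {path}")
    return [
        ResidueRsaRecord(str(p), str(c), int(pos), float(r))
        for p, c, pos, r in zip(df[cols[0]], df[cols[1]], df[cols[2]], df[cols[3]])
    ]


# ---------------------------------------------------------------------------
# Location rules
# ---------------------------------------------------------------------------


def assign_rsa_location(rsa: float) -> ResidueLocation:
    """Classify a residue by relative solvent accessibility (percent).

    Below 5% the residue is buried (core); above 15% it is solvent exposed
    (surface); the band in between is ambiguous and stays unresolved.
    """
    if rsa < 0:
        raise ValueError(f"RSA must be non-negative, got {rsa}")
    if rsa < CORE_RSA_THRESHOLD:
        return ResidueLocation.CORE
    if rsa > SURFACE_RSA_THRESHOLD:
        return ResidueLocation.SURFACE
    return ResidueLocation.UNRESOLVED


def consensus_location(labels: Sequence[ResidueLocation]) -> ResidueLocation:
    """Strict-majority consensus over per-chain core/surface calls.

    Unresolved votes are discarded first; an exact tie (or nothing left)
    stays unresolved.
    """
    if len(labels) == 0:
        raise ValueError("consensus over an empty label list is undefined")
    counts = Counter(
        lab for lab in labels if lab is not ResidueLocation.UNRESOLVED
    )
    n_core = counts.get(ResidueLocation.CORE, 0)
    n_surface = counts.get(ResidueLocation.SURFACE, 0)
    if n_core > n_surface:
        return ResidueLocation.CORE
    if n_surface > n_core:
        return ResidueLocation.SURFACE
    return ResidueLocation.UNRESOLVED


# ---------------------------------------------------------------------------
# Filtering and construction
# ---------------------------------------------------------------------------


def _interface_sets(
    records: Iterable[InterfaceRecord],
) -> dict[tuple[str, str], dict[str, set[int]]]:
    sets: dict[tuple[str, str], dict[str, set[int]]] = {}
    for rec in records:
        key = _edge_key(rec.protein_a, rec.protein_b)
        sides = sets.setdefault(key, {key[0]: set(), key[1]: set()})
        sides[rec.protein_a].add(rec.residue_a)
    return sets


def filter_interactions(
    records: Sequence[InterfaceRecord],
    min_residues: int = MIN_INTERFACE_RESIDUES,
) -> list[InterfaceRecord]:
    """Keep only interactions with >= ``min_residues`` distinct interface
    positions on *both* partners; all records of dropped edges are removed.
    """
    sets = _interface_sets(records)
    keep = {
        key
        for key, sides in sets.items()
        if all(len(p) >= min_residues for p in sides.values())
    }
    return [
        rec
        for rec in records
        if _edge_key(rec.protein_a, rec.protein_b) in keep
    ]


def build_network(
    records: Sequence[InterfaceRecord],
    rsa: Sequence[ResidueRsaRecord],
    *,
    include_self_loops: bool = False,
) -> StructurallyResolvedNetwork:
    """Assemble the structurally resolved network.

    ``records`` should already have passed :func:`filter_interactions`.
    Interface membership overrides the RSA-derived core/surface label;
    residues that only appear in interface sets of edges absent from the
    final graph fall back to their RSA-derived labels.

    Self-interactions (both partners identical) are excluded by default
    because self-loops have no defined centrality semantics here.
    """
    sets = _interface_sets(records)
    if not include_self_loops:
        dropped_self = [k for k in sets if k[0] == k[1]]
        for key in dropped_self:
            logger.warning("dropping self-interaction %s-%s", *key)
            del sets[key]

    graph = nx.Graph()
    for (a, b), sides in sets.items():
        graph.add_edge(a, b)
    node_set = set(graph.nodes)

    interface_map = {
        key: {p: frozenset(pos) for p, pos in sides.items()}
        for key, sides in sets.items()
    }

    # RSA-derived labels via per-chain consensus
    by_residue: dict[tuple[str, int], list[ResidueLocation]] = defaultdict(list)
    for rec in rsa:
        by_residue[(rec.protein, rec.position)].append(
            assign_rsa_location(rec.rsa)
        )
    location_map: dict[str, dict[int, ResidueLocation]] = defaultdict(dict)
    for (protein, position), labels in by_residue.items():
        location_map[protein][position] = consensus_location(labels)

    # Interface membership (retained edges only) takes precedence
    for key, sides in interface_map.items():
        for protein, positions in sides.items():
            if protein not in node_set:  # defensive; cannot happen post-filter
                logger.warning(
                    "interface annotation for %s refers to a protein absent "
                    "from the filtered network; dropping",
                    protein,
                )
                continue
            for pos in positions:
                location_map[protein][pos] = ResidueLocation.INTERFACE

    return StructurallyResolvedNetwork(
        graph=graph,
        interface_map=interface_map,
        location_map=dict(location_map),
    )


def build_resolved_network(
    interface_path: str | Path,
    rsa_path: str | Path,
    *,
    min_residues: int = MIN_INTERFACE_RESIDUES,
    dialect: str | None = None,
) -> StructurallyResolvedNetwork:
    """Parse, filter and build in one call."""
    records = parse_interface_table(interface_path, dialect=dialect)
    filtered = filter_interactions(records, min_residues=min_residues)
    return build_network(filtered, read_rsa_table(rsa_path))
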