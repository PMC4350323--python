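"""Pathway collections with activator/repressor gene roles.

A signaling pathway is modelled as a named gene set in which every member
gene carries an activator/repressor role (ARR) coefficient describing how
the gene's expression relates to pathway activation: products that drive
the pathway get positive coefficients, inhibitors negative ones, and genes
of unclear role zero.  The coefficient takes one of five discrete levels,

    activator         +1.0
    rather_activator  +0.5
    unknown            0.0
    rather_repressor  -0.5
    repressor         -1.0

so that a pathway activation score can weight each gene's expression change
by both direction and confidence of its role.

Collections are stored in a three-column tab-separated dialect
(``pathway_id<TAB>gene_symbol<TAB>role``) because the ubiquitous GMT gene-set
format has no per-gene payload; a GMT importer that marks every gene as a
full activator is provided for plain gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "ARR_LEVELS",
    "ROLE_TO_ARR",
    "PathwayDefinition",
    "PathwayCollection",
    "PathwayFileError",
    "load_pathway_collection",
    "write_pathway_collection",
    "load_gmt",
]

ROLE_TO_ARR: Mapping[str, float] = {
    "activator": 1.0,
    "rather_activator": 0.5,
    "unknown": 0.0,
    "rather_repressor": -0.5,
    "repressor": -1.0,
}
ARR_TO_ROLE = {v: k for k, v in ROLE_TO_ARR.items()}
ARR_LEVELS = frozenset(ROLE_TO_ARR.values())


class PathwayFileError(ValueError):
    """Raised for malformed pathway-definition files."""


@dataclass
class PathwayDefinition:
    """A named gene set with per-gene activator/repressor coefficients.

    Parameters
    ----------
    pathway_id
        Short unique token identifying the pathway.
    display_name
        Free-text human readable name.
    gene_roles
        Mapping gene symbol -> ARR coefficient.  Gene symbols are opaque,
        case-sensitive strings; no alias resolution is attempted.
    """

    pathway_id: str
    display_name: str
    gene_roles: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be non-empty")
        if not self.gene_roles:
            raise ValueError(f"pathway {self.pathway_id!r}: gene_roles must be non-empty")
        bad = {g: c for g, c in self.gene_roles.items() if c not in ARR_LEVELS}
        if bad:
            raise ValueError(
                f"pathway {self.pathway_id!r}: ARR coefficients outside "
                f"{sorted(ARR_LEVELS)}: {bad}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.gene_roles)

    def __len__(self) -> int:
        return len(self.gene_roles)


@dataclass
class PathwayCollection:
    """Ordered list of pathways with unique ids."""

    pathways: list[PathwayDefinition]
    collection_name: str = "collection"

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("PathwayCollection must contain at least one pathway")
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dupes}")

    def __iter__(self) -> Iterator[PathwayDefinition]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out.update(p.gene_roles)
        return out


def load_pathway_collection(path: str | Path) -> PathwayCollection:
    """Read a pathway collection from the 3-column TSV dialect.

    The file must start with a header line; ``#`` lines are comments.  Role
    tokens are mapped to ARR coefficients via :data:`ROLE_TO_ARR`.  Pathway
    order and within-pathway gene order follow the file.

    Raises
    ------
    PathwayFileError
        On unknown role tokens (naming the offending line), duplicate
        (pathway, gene) pairs, ragged rows, or an empty file.
    """
    path = Path(path)
    order: list[str] = []
    roles: dict[str, dict[str, float]] = {}
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # header content is not interpreted
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PathwayFileError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            pid, gene, role = (p.strip() for p in parts)
            if role not in ROLE_TO_ARR:
                raise PathwayFileError(
                    f"{path}:{lineno}: unknown role token {role!r} "
                    f"(expected one of {sorted(ROLE_TO_ARR)})"
                )
            if pid not in roles:
                roles[pid] = {}
                order.append(pid)
            if gene in roles[pid]:
                raise PathwayFileError(
                    f"{path}:{lineno}: gene {gene!r} listed twice in pathway {pid!r}"
                )
            roles[pid][gene] = ROLE_TO_ARR[role]
    if not order:
        raise PathwayFileError(f"{path}: no pathway rows found")
    pathways = [
        PathwayDefinition(pathway_id=pid, display_name=pid, gene_roles=roles[pid])
        for pid in order
    ]
    return PathwayCollection(pathways=pathways, collection_name=path.stem)


def write_pathway_collection(collection: PathwayCollection, path: str | Path) -> None:
    """Write ``collection`` in the 3-column TSV dialect (round-trips with load)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pathway_id\tgene_symbol\trole\n")
        for p in collection:
            for gene, coef in p.gene_roles.items():
                fh.write(f"{p.pathway_id}\t{gene}\t{ARR_TO_ROLE[coef]}\n")


def load_gmt(path: str | Path) -> PathwayCollection:
    """Import a standard GMT file, assigning ARR = +1.0 (activator) to every gene.

    GMT rows are ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a set are an error, as in the native dialect.
    """
    path = Path(path)
    pathways: list[PathwayDefinition] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PathwayFileError(
                    f"{path}:{lineno}: GMT rows need name, description and >=1 gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if len(set(genes)) != len(genes):
                raise PathwayFileError(f"{path}:{lineno}: duplicate genes in set {name!r}")
            pathways.append(
                PathwayDefinition(
                    pathway_id=name,
                    display_name=parts[1] or name,
                    gene_roles={g: 1.0 for g in genes},
                )
            )
    if not pathways:
        raise PathwayFileError(f"{path}: empty GMT file")
    return PathwayCollection(pathways=pathways, collection_name=path.stem)
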