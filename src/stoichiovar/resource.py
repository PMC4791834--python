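"""Protein complex definitions: loading, ranking, redundancy filtering, decoys.

A *complex resource* is an ordered collection of named protein sets drawn from
curated sources (manual curation, COMPLEAT, CORUM, or user supplied).  Sources
carry a rank used during redundancy filtering: when two complexes overlap
heavily, the one from the more trusted source (and, within a source, the
larger one) is kept.  Decoy resources randomly reassign the same protein pool
to complexes of the same sizes and serve as a null model for variable-member
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Source ranking used during redundancy filtering (lower = higher priority).
SOURCE_RANK = {"manual": 0, "compleat": 1, "corum": 2, "user": 3}


class ResourceParseError(ValueError):
    """Raised when a complex definition file cannot be parsed."""


@dataclass(frozen=True)
class ComplexDefinition:
    """A single named protein complex.

    Parameters
    ----------
    complex_id : unique identifier within a resource.
    name : human-readable description (may equal the id).
    source : one of ``manual``, ``compleat``, ``corum``, ``user``.
    members : set of protein identifiers; non-empty, duplicates collapse.
    """

    complex_id: str
    name: str
    source: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.source not in SOURCE_RANK:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {sorted(SOURCE_RANK)}"
            )
        if not self.members:
            raise ValueError(f"complex {self.complex_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def rank_key(self) -> tuple:
        """Sort key: source rank, then size descending, then id."""
        return (SOURCE_RANK[self.source], -self.size, self.complex_id)


class ComplexResource:
    """Ordered collection of :class:`ComplexDefinition` with an inverse index."""

    def __init__(self, complexes: Iterable[ComplexDefinition]):
        self.complexes: list[ComplexDefinition] = list(complexes)
        ids = [c.complex_id for c in self.complexes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate complex ids: {dupes}")
        self._by_id = {c.complex_id: c for c in self.complexes}

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[ComplexDefinition]:
        return iter(self.complexes)

    def __getitem__(self, complex_id: str) -> ComplexDefinition:
        return self._by_id[complex_id]

    def __contains__(self, complex_id: str) -> bool:
        return complex_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [c.complex_id for c in self.complexes]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.complexes]

    @property
    def proteins(self) -> set:
        """Union of all members."""
        out: set = set()
        for c in self.complexes:
            out |= c.members
        return out

    @property
    def index(self) -> dict:
        """protein -> list of complex_ids containing it (resource order)."""
        idx: dict[str, list[str]] = {}
        for c in self.complexes:
            for p in sorted(c.members):
                idx.setdefault(p, []).append(c.complex_id)
        return idx

    def membership_table(self) -> pd.DataFrame:
        """Long-format view: one row per (complex_id, protein_id)."""
        rows = [
            (c.complex_id, p, c.source)
            for c in self.complexes
            for p in sorted(c.members)
        ]
        return pd.DataFrame(rows, columns=["complex_id", "protein_id", "source"])


def read_complexes(path, source: str = "user", fmt: str | None = None) -> ComplexResource:
    """Read complex definitions from a GMT or long-format TSV file.

    GMT: one complex per line -- ``id <tab> description <tab> member...``.
    TSV: two or three columns -- ``complex_id <tab> protein_id [<tab> source]``;
    a header row naming the first column ``complex_id`` is skipped.

    ``fmt`` may be ``"gmt"`` or ``"tsv"``; by default it is inferred from the
    file extension (``.gmt`` -> GMT, anything else -> TSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    if not any(ln.strip() for ln in lines):
        raise ResourceParseError(f"{path}: file is empty")

    complexes: list[ComplexDefinition] = []
    if fmt == "gmt":
        for i, ln in enumerate(lines, start=1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ResourceParseError(
                    f"{path}: line {i}: expected id, description and >=1 member"
                )
            cid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ResourceParseError(f"{path}: line {i}: complex has no members")
            complexes.append(ComplexDefinition(cid, desc, source, frozenset(members)))
    elif fmt == "tsv":
        order: list[str] = []
        groups: dict[str, set] = {}
        src: dict[str, str] = {}
        for i, ln in enumerate(lines, start=1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if i == 1 and parts[0] == "complex_id":
                continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ResourceParseError(
                    f"{path}: line {i}: expected complex_id and protein_id columns"
                )
            cid, pid = parts[0], parts[1]
            if cid not in groups:
                order.append(cid)
                groups[cid] = set()
                src[cid] = parts[2] if len(parts) > 2 and parts[2] else source
            groups[cid].add(pid)
        complexes = [
            ComplexDefinition(cid, cid, src[cid], frozenset(groups[cid])) for cid in order
        ]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ComplexResource(complexes)


def write_gmt(resource: ComplexResource, path) -> None:
    """Write a resource in GMT format (members sorted for determinism)."""
    with open(path, "w") as fh:
        for c in resource:
            fh.write("\t".join([c.complex_id, c.name, *sorted(c.members)]) + "\n")


def filter_redundant(
    resource: ComplexResource,
    overlap_threshold: float = 0.5,
    min_members: int = 5,
) -> ComplexResource:
    """Greedy redundancy filter over ranked complexes.

    Complexes smaller than ``min_members`` are removed first.  The remainder
    are ranked by (source rank, member count descending, complex_id) and
    scanned in order: a complex is kept unless it shares at least
    ``overlap_threshold`` of *its own* members with an already-kept complex.
    The conservative reading of the 50 % rule removes near-subsets of a kept
    representative.
    """
    if not (0 < overlap_threshold <= 1):
        raise ValueError("overlap_threshold must be in (0, 1]")
    candidates = sorted(
        (c for c in resource if c.size >= min_members), key=lambda c: c.rank_key
    )
    kept: list[ComplexDefinition] = []
    for cand in candidates:
        redundant = any(
            len(cand.members & k.members) / cand.size >= overlap_threshold
            for k in kept
        )
        if not redundant:
            kept.append(cand)
    return ComplexResource(kept)


def generate_decoys(resource: ComplexResource, seed: int) -> ComplexResource:
    """Size-preserving random reassignment of the protein pool to complexes.

    The concatenated membership list is permuted and re-cut into complexes of
    the original sizes; within-complex duplicates are resolved by swapping the
    duplicated entry with a random position in another complex.  The multiset
    of protein occurrences and the vector of complex sizes are preserved
    exactly, and the output is a deterministic function of ``seed``.
    """
    if len(resource) == 0:
        raise ValueError("cannot generate decoys from an empty resource")
    sizes = resource.sizes
    pool = [p for c in resource for p in sorted(c.members)]
    counts = pd.Series(pool).value_counts()
    if counts.max() > len(resource):
        offender = counts.idxmax()
        raise ValueError(
            f"protein {offender!r} occurs {counts.max()} times but there are only "
            f"{len(resource)} complexes; duplicate-free decoys are impossible"
        )
    rng = np.random.default_rng(seed)
    flat = [pool[i] for i in rng.permutation(len(pool))]
    # complex index of every flat position
    bounds = np.cumsum([0] + sizes)
    cidx = np.empty(len(flat), dtype=int)
    for i in range(len(sizes)):
        cidx[bounds[i] : bounds[i + 1]] = i
    flat, cidx = _repair_duplicates(flat, cidx, len(sizes), rng)
    defs = []
    for i, c in enumerate(resource):
        members = frozenset(flat[j] for j in range(len(flat)) if cidx[j] == i)
        defs.append(
            ComplexDefinition(c.complex_id, f"decoy:{c.name}", c.source, members)
        )
    return ComplexResource(defs)


def _repair_duplicates(flat, cidx, n_complexes, rng, max_tries_factor: int = 20000):
    """Swap duplicated within-complex entries with random positions elsewhere."""
    n = len(flat)
    max_tries = max_tries_factor * max(n, 1)
    tries = 0
    while True:
        dup_pos = _find_duplicate(flat, cidx, n_complexes)
        if dup_pos is None:
            return flat, cidx
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("decoy duplicate repair did not converge")
            j = int(rng.integers(n))
            if cidx[j] == cidx[dup_pos]:
                continue
            # swap must not create a duplicate on either side
            members_here = {flat[k] for k in range(n) if cidx[k] == cidx[dup_pos] and k != dup_pos}
            members_there = {flat[k] for k in range(n) if cidx[k] == cidx[j] and k != j}
            if flat[j] not in members_here and flat[dup_pos] not in members_there:
                flat[dup_pos], flat[j] = flat[j], flat[dup_pos]
                break


def _find_duplicate(flat, cidx, n_complexes):
    seen: list[set] = [set() for _ in range(n_complexes)]
    for pos, (p, ci) in enumerate(zip(flat, cidx)):
        if p in seen[ci]:
            return pos
        seen[ci].add(p)
    return None


def map_orthologs(resource: ComplexResource, ortholog_table: Mapping | pd.DataFrame) -> ComplexResource:
    """Replace members by their orthologs via a (possibly one-to-many) mapping.

    ``ortholog_table`` is either a mapping ``source_id -> target_id(s)`` or a
    two-column DataFrame ``(source_id, target_id)``.  Unmapped members are
    dropped; one-to-many mappings expand to all targets; complexes whose
    membership becomes empty are removed.
    """
    mapping: dict[str, set] = {}
    if isinstance(ortholog_table, pd.DataFrame):
        src_col, tgt_col = ortholog_table.columns[:2]
        for s, t in zip(ortholog_table[src_col], ortholog_table[tgt_col]):
            mapping.setdefault(str(s), set()).add(str(t))
    else:
        for s, t in ortholog_table.items():
            targets = {t} if isinstance(t, str) else set(t)
            mapping.setdefault(str(s), set()).update(targets)
    defs = []
    for c in resource:
        members: set = set()
        for p in c.members:
            members |= mapping.get(p, set())
        if members:
            defs.append(ComplexDefinition(c.complex_id, c.name, c.source, frozenset(members)))
    return ComplexResource(defs)


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a two-column (source_id, target_id) TSV; a header row is skipped."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.iloc[0, 0] in ("source_id", "source", "from"):
        df = df.iloc[1:]
    df.columns = ["source_id", "target_id"][: df.shape[1]] + list(df.columns[2:])
    return df[["source_id", "target_id"]].reset_index(drop=True)


def restrict_to_quantified(
    resource: ComplexResource,
    quantified: Iterable[str],
    min_members: int = 5,
) -> ComplexResource:
    """Intersect memberships with the quantified proteins; drop small complexes.

    Only complexes retaining at least ``min_members`` quantified members are
    kept, mirroring the requirement that a complex have enough quantified
    subunits for the normalization to be meaningful.
    """
    quantified = set(quantified)
    defs = []
    for c in resource:
        members = c.members & quantified
        if len(members) >= min_members:
            defs.append(ComplexDefinition(c.complex_id, c.name, c.source, frozenset(members)))
    return ComplexResource(defs)
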