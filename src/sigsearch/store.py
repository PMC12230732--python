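"""Signature libraries: GMT parsing, up/down pairing, metadata, and the bit-vector index.

A *signature* is the transcriptomic consequence of one perturbation (a compound
or a CRISPR knockout) in one context (cell line, time point, concentration),
represented as a paired up-regulated and down-regulated gene set.  Libraries are
exchanged as GMT files in which each signature contributes two lines whose
labels share a base and end in a trailing ``up`` / ``down`` direction token,
e.g. ``RAD001_HCC515_6H_H14_camptothecin_10 uM down``.

The search substrate is a :class:`BitIndex`: one packed bit row per stored gene
set over a fixed, lexicographically ordered gene universe, so that overlaps are
computed with bitwise AND + popcount.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GeneSet",
    "GeneUniverse",
    "SignatureMeta",
    "SignaturePair",
    "BitIndex",
    "MalformedGMTError",
    "DuplicateLabelError",
    "UnparseableLabelError",
    "EmptyUniverseError",
    "OverlappingPairWarning",
    "parse_gmt",
    "write_gmt",
    "split_direction",
    "parse_signature_label",
    "pair_signatures",
    "build_universe",
    "build_bit_index",
]


class MalformedGMTError(ValueError):
    """A GMT line with fewer than three tab-separated fields."""

    def __init__(self, line_number: int, line: str):
        self.line_number = line_number
        super().__init__(
            f"GMT line {line_number} has fewer than 3 tab-separated fields: {line!r}"
        )


class DuplicateLabelError(ValueError):
    """Two sets with the same base label and the same direction."""


class UnparseableLabelError(ValueError):
    """A signature label with fewer than two positional tokens.

    The partially filled :class:`SignatureMeta` (raw label only) is retained
    on the ``meta`` attribute.
    """

    def __init__(self, label: str, meta: "SignatureMeta"):
        self.meta = meta
        super().__init__(f"signature label has fewer than 2 tokens: {label!r}")


class EmptyUniverseError(ValueError):
    """No gene symbols available to build a universe from."""


class OverlappingPairWarning(UserWarning):
    """A signature's up and down sets shared genes; the shared genes were removed."""


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols (symbols are uppercased at parse time)."""

    label: str
    members: frozenset[str]
    description: str = ""

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SignatureMeta:
    """Context metadata parsed from a signature label.

    Labels are underscore-delimited with positional tokens
    ``batch_cellline_time_well_perturbation_concentration`` followed by a
    trailing direction token.  Trailing tokens may be absent; unknown extra
    tokens are kept verbatim in ``concentration``.
    """

    signature_id: str
    perturbation: str = ""
    perturbation_kind: str = "chemical"  # "chemical" | "crispr_ko"
    cell_line: str = ""
    time_point: str = ""
    concentration: str = ""
    batch: str = ""
    well: str = ""
    fda_approved: bool = False
    direction: Optional[str] = None  # "up" | "down"; None at pair level


@dataclass(frozen=True)
class SignaturePair:
    """One perturbation-in-context: metadata plus an up set and a down set."""

    meta: SignatureMeta
    up: GeneSet
    down: GeneSet

    def __post_init__(self) -> None:
        shared = self.up.members & self.down.members
        if shared:
            raise ValueError(
                f"up/down sets of {self.meta.signature_id!r} share genes: {sorted(shared)}"
            )


_DIRECTION_RE = re.compile(r"^(?P<base>.+?)[\s_](?P<direction>up|down)\s*$", re.IGNORECASE)


def parse_gmt(stream: Iterable[str]) -> list[GeneSet]:
    """Parse GMT lines into :class:`GeneSet` records.

    Each line must carry at least ``label<TAB>description<TAB>gene...``.  Empty
    gene tokens are dropped, symbols uppercased, duplicates collapsed.  An empty
    stream yields an empty list.
    """
    sets: list[GeneSet] = []
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise MalformedGMTError(i, line)
        label, description = fields[0], fields[1]
        members = frozenset(tok.strip().upper() for tok in fields[2:] if tok.strip())
        sets.append(GeneSet(label=label, members=members, description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], handle: IO[str]) -> None:
    """Write gene sets as GMT lines; members are sorted for byte determinism."""
    for gs in sets:
        genes = "\t".join(sorted(gs.members))
        handle.write(f"{gs.label}\t{gs.description or 'na'}\t{genes}\n")


def split_direction(label: str) -> tuple[str, Optional[str]]:
    """Split a trailing ``up``/``down`` token (space- or underscore-separated,
    case-insensitive) off a label.  Returns ``(base, direction-or-None)``."""
    m = _DIRECTION_RE.match(label)
    if m is None:
        return label, None
    return m.group("base"), m.group("direction").lower()


def parse_signature_label(
    label: str,
    ko_genes: Optional[Iterable[str]] = None,
    fda_compounds: Optional[Iterable[str]] = None,
) -> SignatureMeta:
    """Parse an underscore-delimited signature label into :class:`SignatureMeta`.

    Positional tokens: batch, cell_line, time_point, well, perturbation,
    concentration; missing trailing tokens become empty strings, extra tokens
    are folded verbatim into the concentration field.  ``perturbation_kind`` is
    ``crispr_ko`` when the perturbation appears in *ko_genes* (case-insensitive),
    otherwise ``chemical``; ``fda_approved`` is set from *fda_compounds*.

    Raises :class:`UnparseableLabelError` (carrying a raw-label-only meta) when
    fewer than two positional tokens are present.
    """
    base, direction = split_direction(label)
    tokens = [t for t in base.split("_")]
    if len(tokens) < 2:
        raise UnparseableLabelError(label, SignatureMeta(signature_id=label, direction=direction))
    padded = tokens + [""] * (6 - len(tokens))
    batch, cell_line, time_point, well, perturbation = padded[:5]
    concentration = "_".join(padded[5:]) if len(tokens) > 6 else padded[5]
    ko = {g.upper() for g in ko_genes} if ko_genes else set()
    fda = {c.lower() for c in fda_compounds} if fda_compounds else set()
    kind = "crispr_ko" if perturbation.upper() in ko else "chemical"
    return SignatureMeta(
        signature_id=label,
        perturbation=perturbation,
        perturbation_kind=kind,
        cell_line=cell_line,
        time_point=time_point,
        concentration=concentration,
        batch=batch,
        well=well,
        fda_approved=perturbation.lower() in fda,
        direction=direction,
    )


def pair_signatures(
    sets: Sequence[GeneSet],
    ko_genes: Optional[Iterable[str]] = None,
    fda_compounds: Optional[Iterable[str]] = None,
) -> tuple[list[SignaturePair], list[GeneSet]]:
    """Pair up/down gene sets sharing a base label into signatures.

    Returns ``(pairs, unpaired)``.  Sets whose label has no recognizable
    direction token, or whose partner is missing, are reported as unpaired and
    excluded.  Two same-direction sets with one base label raise
    :class:`DuplicateLabelError`.  Genes shared between a pair's up and down
    sets are removed from both with an :class:`OverlappingPairWarning`, keeping
    mimicker/reverser tables well defined.
    """
    by_base: dict[str, dict[str, GeneSet]] = {}
    undirected: list[GeneSet] = []
    order: list[str] = []
    for gs in sets:
        base, direction = split_direction(gs.label)
        if direction is None:
            undirected.append(gs)
            continue
        slot = by_base.setdefault(base, {})
        if not slot:
            order.append(base)
        if direction in slot:
            raise DuplicateLabelError(
                f"two {direction!r} sets share the base label {base!r}"
            )
        slot[direction] = gs

    pairs: list[SignaturePair] = []
    unpaired: list[GeneSet] = list(undirected)
    for base in order:
        slot = by_base[base]
        if "up" not in slot or "down" not in slot:
            unpaired.extend(slot.values())
            continue
        up, down = slot["up"], slot["down"]
        shared = up.members & down.members
        if shared:
            warnings.warn(
                f"{base!r}: {len(shared)} genes appear in both the up and down set; removed",
                OverlappingPairWarning,
                stacklevel=2,
            )
            up = dataclasses.replace(up, members=up.members - shared)
            down = dataclasses.replace(down, members=down.members - shared)
        try:
            meta = parse_signature_label(base + " up", ko_genes, fda_compounds)
        except UnparseableLabelError as err:
            meta = err.meta
        # pair-level meta: base label as the id, direction unset
        meta = dataclasses.replace(
            meta,
            signature_id=base,
            direction=None,
            perturbation=meta.perturbation or base,
        )
        pairs.append(SignaturePair(meta=meta, up=up, down=down))
    return pairs, unpaired


class GeneUniverse:
    """The ordered background vocabulary of gene symbols.

    Defines bit positions for the index and the fourth margin (background) of
    the Fisher contingency table.
    """

    def __init__(self, symbols: Sequence[str]):
        syms = tuple(symbols)
        if not syms:
            raise EmptyUniverseError("cannot build a universe from zero symbols")
        if len(set(syms)) != len(syms):
            raise ValueError("universe symbols must be unique")
        self.symbols: tuple[str, ...] = syms
        self.index_of: dict[str, int] = {s: i for i, s in enumerate(syms)}

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def nbytes(self) -> int:
        return (self.size + 7) // 8

    def resolve(self, symbols: Iterable[str]) -> tuple[list[str], list[str]]:
        """Split symbols into (resolved, unresolved) against this universe."""
        resolved, unresolved = [], []
        for s in symbols:
            (resolved if s.upper() in self.index_of else unresolved).append(s.upper())
        return resolved, unresolved

    def mask(self, symbols: Iterable[str]) -> np.ndarray:
        """Packed (uint8, big-endian bit order) membership mask for *symbols*;
        symbols outside the universe are silently ignored."""
        bits = np.zeros(self.size, dtype=bool)
        for s in symbols:
            i = self.index_of.get(s.upper())
            if i is not None:
                bits[i] = True
        return np.packbits(bits)

    def unmask(self, mask: np.ndarray) -> frozenset[str]:
        """Invert :meth:`mask`: the symbols whose bits are set."""
        bits = np.unpackbits(mask, count=self.size).astype(bool)
        return frozenset(self.symbols[i] for i in np.flatnonzero(bits))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneUniverse) and self.symbols == other.symbols

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:
        return f"GeneUniverse(size={self.size})"


def build_universe(
    pairs: Sequence[SignaturePair], extra: Optional[Iterable[str]] = None
) -> GeneUniverse:
    """Sorted union of all member symbols across *pairs* plus *extra* symbols."""
    if not pairs:
        raise EmptyUniverseError("need at least one signature pair")
    union: set[str] = set()
    for p in pairs:
        union |= p.up.members
        union |= p.down.members
    if extra is not None:
        union |= {s.upper() for s in extra}
    if not union:
        raise EmptyUniverseError("signature pairs contain no genes")
    return GeneUniverse(sorted(union))


_INDEX_FORMAT_VERSION = 1


class BitIndex:
    """Packed membership bit-rows for every stored gene set over a universe.

    Rows are ordered pair by pair: row ``2k`` is pair *k*'s up set, row
    ``2k + 1`` its down set.  ``pair_links[r]`` gives the partner row of row
    *r*.  Overlap against a query mask is ``popcount(row AND mask)``.
    """

    def __init__(
        self,
        universe: GeneUniverse,
        rows: np.ndarray,
        row_meta: Sequence[tuple[SignatureMeta, str]],
        pair_links: np.ndarray,
        dropped_symbols: int = 0,
    ):
        if rows.ndim != 2 or rows.shape[1] != universe.nbytes:
            raise ValueError("row array shape does not match the universe")
        if rows.shape[0] != len(row_meta):
            raise ValueError("row_meta length does not match the row count")
        self.universe = universe
        self.rows = np.ascontiguousarray(rows, dtype=np.uint8)
        self.row_meta = list(row_meta)
        self.pair_links = np.asarray(pair_links, dtype=np.int64)
        self.dropped_symbols = int(dropped_symbols)
        self._popcounts = np.bitwise_count(self.rows).sum(axis=1).astype(np.int64)

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_rows // 2

    @property
    def set_sizes(self) -> np.ndarray:
        """popcount of every row (resolved member counts)."""
        return self._popcounts

    def perturbations(self) -> list[str]:
        """Distinct perturbation names in row order of first appearance."""
        seen: dict[str, None] = {}
        for meta, _ in self.row_meta:
            seen.setdefault(meta.perturbation, None)
        return list(seen)

    def overlap_counts(self, mask: np.ndarray) -> np.ndarray:
        """popcount(row AND mask) for every row; *mask* must match the universe."""
        if mask.shape[-1] != self.rows.shape[1]:
            raise ValueError("mask length does not match the index universe")
        return np.bitwise_count(self.rows & mask[np.newaxis, :]).sum(axis=1).astype(np.int64)

    def row_genes(self, row: int, mask: Optional[np.ndarray] = None) -> frozenset[str]:
        """Symbols of row *row*, optionally intersected with a query mask."""
        r = self.rows[row]
        if mask is not None:
            r = r & mask
        return self.universe.unmask(r)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to an ``.npz`` container; round-trips bit-exactly."""
        meta_json = json.dumps(
            [
                {"role": role, **dataclasses.asdict(meta)}
                for meta, role in self.row_meta
            ]
        )
        np.savez_compressed(
            path,
            version=np.int64(_INDEX_FORMAT_VERSION),
            symbols=np.array(self.universe.symbols, dtype=np.str_),
            rows=self.rows,
            pair_links=self.pair_links,
            dropped_symbols=np.int64(self.dropped_symbols),
            row_meta=np.array(meta_json, dtype=np.str_),
        )

    @classmethod
    def load(cls, path) -> "BitIndex":
        with np.load(path, allow_pickle=False) as z:
            version = int(z["version"])
            if version != _INDEX_FORMAT_VERSION:
                raise ValueError(f"unsupported index format version {version}")
            universe = GeneUniverse([str(s) for s in z["symbols"]])
            records = json.loads(str(z["row_meta"]))
            row_meta = [
                (SignatureMeta(**{k: v for k, v in rec.items() if k != "role"}), rec["role"])
                for rec in records
            ]
            return cls(
                universe,
                z["rows"],
                row_meta,
                z["pair_links"],
                int(z["dropped_symbols"]),
            )


def build_bit_index(pairs: Sequence[SignaturePair], universe: GeneUniverse) -> BitIndex:
    """Pack every pair's up and down set into bit rows over *universe*.

    Symbols absent from the universe are dropped; the total dropped count is
    reported on ``BitIndex.dropped_symbols``.
    """
    if not pairs:
        raise ValueError("cannot index an empty pair sequence")
    n_rows = 2 * len(pairs)
    rows = np.zeros((n_rows, universe.nbytes), dtype=np.uint8)
    row_meta: list[tuple[SignatureMeta, str]] = []
    pair_links = np.zeros(n_rows, dtype=np.int64)
    dropped = 0
    for k, pair in enumerate(pairs):
        for offset, (gs, role) in enumerate(((pair.up, "up"), (pair.down, "down"))):
            r = 2 * k + offset
            resolved, unresolved = universe.resolve(gs.members)
            dropped += len(unresolved)
            rows[r] = universe.mask(resolved)
            row_meta.append(
                (dataclasses.replace(pair.meta, signature_id=gs.label, direction=role), role)
            )
        pair_links[2 * k] = 2 * k + 1
        pair_links[2 * k + 1] = 2 * k
    return BitIndex(universe, rows, row_meta, pair_links, dropped)
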