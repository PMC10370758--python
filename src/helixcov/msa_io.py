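"""Alignment and per-pair-statistics I/O.

Reads and writes Stockholm 1.0 (with the ``#=GC SS_cons`` consensus-structure
line) and plain FASTA, applies the gappy-column filter, and imports/exports
tab-separated per-pair statistics tables so the aggregation layer can run on
externally computed covariation output.

Coordinates are 1-based alignment columns in every file format; a filtered
:class:`Alignment` keeps a ``column_map`` back to the original columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

GAP_CHARS = frozenset("-.~")
_ALPHABET = frozenset("ACGUTN-.~")

#: integer encoding used throughout: A=0 C=1 G=2 U=3, 4 = gap or N (missing)
_ENCODE = {c: i for i, c in enumerate("ACGU")}


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged rows, duplicate names, bad symbols)."""


@dataclass
class Alignment:
    """A gapped RNA multiple sequence alignment.

    Parameters
    ----------
    names : list of str
        Unique sequence identifiers.
    rows : list of str
        Gapped, uppercased RNA strings (T already normalised to U), one per
        name, all of identical length.
    ss_cons : str or None
        Optional WUSS consensus structure of the same length.
    column_map : list of int or None
        For a column-filtered alignment, the original 1-based column index of
        each retained column (strictly increasing). ``None`` means identity.
    """

    names: list[str]
    rows: list[str]
    ss_cons: str | None = None
    column_map: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentFormatError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentFormatError(f"duplicate sequence names: {dupes}")
        if self.rows:
            L = len(self.rows[0])
            for name, row in zip(self.names, self.rows):
                if len(row) != L:
                    raise AlignmentFormatError(
                        f"ragged alignment: sequence {name!r} has length "
                        f"{len(row)}, expected {L}"
                    )
        if self.ss_cons is not None and self.rows and len(self.ss_cons) != len(self.rows[0]):
            raise AlignmentFormatError(
                f"SS_cons length {len(self.ss_cons)} != alignment length {len(self.rows[0])}"
            )
        if self.column_map is not None:
            cm = self.column_map
            if any(b <= a for a, b in zip(cm, cm[1:])):
                raise AlignmentFormatError("column_map must be strictly increasing")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def original_column(self, col: int) -> int:
        """Map a current 1-based column index to its original 1-based index."""
        if self.column_map is None:
            return col
        return self.column_map[col - 1]

    def to_matrix(self) -> np.ndarray:
        """Encode as an (n_seqs, length) uint8 matrix; A,C,G,U -> 0..3, else 4."""
        mat = np.full((self.n_seqs, self.length), 4, dtype=np.uint8)
        for r, row in enumerate(self.rows):
            for c, ch in enumerate(row):
                mat[r, c] = _ENCODE.get(ch, 4)
        return mat

    def gap_matrix(self) -> np.ndarray:
        """Boolean (n_seqs, length) matrix marking gap characters ('-', '.', '~')."""
        out = np.zeros((self.n_seqs, self.length), dtype=bool)
        for r, row in enumerate(self.rows):
            for c, ch in enumerate(row):
                out[r, c] = ch in GAP_CHARS
        return out


def _normalize_row(name: str, seq: str) -> str:
    row = seq.upper().replace("T", "U")
    bad = set(row) - _ALPHABET
    if bad:
        raise AlignmentFormatError(
            f"sequence {name!r} contains unsupported characters: {sorted(bad)}"
        )
    return row


def read_stockholm(path) -> Alignment:
    """Read a single-alignment Stockholm 1.0 file.

    Interleaved blocks are concatenated; a ``#=GC SS_cons`` line (possibly
    wrapped over blocks) becomes ``ss_cons``. Rows are uppercased and T is
    normalised to U.
    """
    try:
        msa = AlignIO.read(path, "stockholm")
    except ValueError as exc:
        raise AlignmentFormatError(str(exc)) from exc
    names = [rec.id for rec in msa]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise AlignmentFormatError(f"duplicate sequence names: {dupes}")
    rows = [_normalize_row(rec.id, str(rec.seq)) for rec in msa]
    ss = msa.column_annotations.get("secondary_structure")
    return Alignment(names=names, rows=rows, ss_cons=ss)


def write_stockholm(aln: Alignment, path) -> None:
    """Write a single-block Stockholm 1.0 file (``read_stockholm`` inverts it)."""
    width = max((len(n) for n in aln.names), default=0)
    width = max(width, len("#=GC SS_cons"))
    buf = io.StringIO()
    buf.write("# STOCKHOLM 1.0\n")
    for name, row in zip(aln.names, aln.rows):
        buf.write(f"{name:<{width}} {row}\n")
    if aln.ss_cons:
        buf.write(f"{'#=GC SS_cons':<{width}} {aln.ss_cons}\n")
    buf.write("//\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file (sequences only, no structure)."""
    msa = AlignIO.read(path, "fasta")
    names = [rec.id for rec in msa]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise AlignmentFormatError(f"duplicate sequence names: {dupes}")
    rows = [_normalize_row(rec.id, str(rec.seq)) for rec in msa]
    return Alignment(names=names, rows=rows)


def filter_gap_columns(aln: Alignment, max_gap_frac: float = 0.7) -> Alignment:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    The 70% default mirrors the standard covariation-analysis practice of
    disregarding alignment columns with more than 70% gaps. '-', '.' and '~'
    count as gaps; 'N' counts as a residue here (it is missing data only for
    the statistics). Base pairs whose partner column is removed become
    unpaired in the surviving ``ss_cons``; ``column_map`` records the
    surviving original 1-based coordinates.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must be in [0, 1]")
    gaps = aln.gap_matrix()
    frac = gaps.mean(axis=0)
    keep = frac <= max_gap_frac
    if not keep.any():
        raise ValueError("empty alignment after filtering")
    keep_idx = np.flatnonzero(keep)
    rows = ["".join(row[c] for c in keep_idx) for row in aln.rows]
    ss = None
    if aln.ss_cons is not None:
        # unpair any base whose partner column was dropped, then subset
        from helixcov.structure import parse_wuss, pairs_to_wuss

        struct = parse_wuss(aln.ss_cons)
        kept = set(int(c) + 1 for c in keep_idx)
        surviving = {(i, j) for (i, j) in struct.pairs if i in kept and j in kept}
        ss_full = list(pairs_to_wuss(type(struct)(pairs=surviving, length=aln.length)))
        # keep non-pairing annotation characters where possible
        for c in range(aln.length):
            if ss_full[c] == "." and aln.ss_cons[c] not in "<>()[]{}":
                if not aln.ss_cons[c].isalpha():
                    ss_full[c] = aln.ss_cons[c]
        ss = "".join(ss_full[c] for c in keep_idx)
    prior = aln.column_map or list(range(1, aln.length + 1))
    column_map = [prior[c] for c in keep_idx]
    return Alignment(names=list(aln.names), rows=rows, ss_cons=ss, column_map=column_map)


@dataclass
class PairStats:
    """Per-base-pair covariation statistics.

    ``p_value`` is the covariation p-value (must be in (0, 1]; producers floor
    at their empirical resolution), ``substitutions`` the Fitch parsimony
    substitution count over the two columns (the Lancaster weight), and
    ``power`` the probability in [0, 1] that a pair with that much variation
    would be detected as significantly covarying (the weighted-Fisher weight
    source).
    """

    score: float
    p_value: float
    substitutions: int
    power: float
    in_proposed_structure: bool = False
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if not 0.0 <= self.power <= 1.0:
            raise ValueError(f"power must be in [0, 1], got {self.power}")
        if self.substitutions < 0:
            raise ValueError("substitutions must be non-negative")


@dataclass
class PairStatsTable:
    """Per-pair statistics keyed by (i, j) original 1-based column pairs, i < j."""

    records: dict[tuple[int, int], PairStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.records:
            if not (0 < i < j):
                raise ValueError(f"pair key must satisfy 0 < i < j, got ({i}, {j})")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: tuple[int, int]) -> PairStats:
        return self.records[key]

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self.records

    def items(self):
        return self.records.items()


_TSV_COLUMNS = ("left_pos", "right_pos", "score", "p_value", "substitutions", "power", "in_structure")


def read_pair_stats_table(path) -> PairStatsTable:
    """Read a per-pair statistics TSV (header: left_pos, right_pos, score,
    p_value, substitutions, power, in_structure)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair-stats table missing columns: {sorted(missing)}")
    records: dict[tuple[int, int], PairStats] = {}
    for row in df.itertuples(index=False):
        i, j = int(row.left_pos), int(row.right_pos)
        if not i < j:
            raise ValueError(f"left_pos must be < right_pos, got ({i}, {j})")
        if (i, j) in records:
            raise ValueError(f"duplicate pair ({i}, {j})")
        ev = getattr(row, "e_value", None)
        records[(i, j)] = PairStats(
            score=float(row.score),
            p_value=float(row.p_value),
            substitutions=int(row.substitutions),
            power=float(row.power),
            in_proposed_structure=bool(row.in_structure),
            e_value=None if ev is None or (isinstance(ev, float) and np.isnan(ev)) else float(ev),
        )
    return PairStatsTable(records=records)


def write_pair_stats_table(table: PairStatsTable, path) -> None:
    """Write a per-pair statistics TSV; inverse of :func:`read_pair_stats_table`."""
    import pandas as pd

    rows = []
    for (i, j), rec in sorted(table.items()):
        row = {
            "left_pos": i,
            "right_pos": j,
            "score": rec.score,
            "p_value": rec.p_value,
            "substitutions": rec.substitutions,
            "power": rec.power,
            "in_structure": int(rec.in_proposed_structure),
        }
        if rec.e_value is not None:
            row["e_value"] = rec.e_value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

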