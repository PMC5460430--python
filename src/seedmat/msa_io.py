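"""Reading seed MSAs and reading/writing substitution-matrix text files.

Seed alignments come in as multi-record Stockholm 1.0 (the Pfam-seed dialect,
where insert states appear as lowercase letters and ``.`` gaps) or as aligned
FASTA.  Parsing is delegated to :mod:`Bio.AlignIO`; this module only
canonicalizes symbols (see :mod:`seedmat.alphabet`) and enforces the
equal-length invariant with actionable error messages.

Matrix files use the whitespace-separated square dialect understood by the
``-matrix``/``-datafile`` options of the common search tools: ``#`` comment
lines, one header row of symbols, then one labelled row of integers per
symbol.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import AlignIO

from . import alphabet
from .errors import (
    MatrixFormatError,
    NoRecordsError,
    RaggedAlignmentError,
)

if TYPE_CHECKING:  # avoid a runtime cycle: logodds -> counting -> msa_io
    from .logodds import SubstitutionMatrix

#: Column order used by default when writing matrix files.
DEFAULT_ALPHABET_ORDER: tuple[str, ...] = tuple(alphabet.EXTENDED)


@dataclass
class GroupAlignment:
    """One seed MSA — a "group" of related sequences.

    ``codes`` is an ``(s_k, L)`` int8 array over the extended alphabet plus
    the gap code; every row has the same aligned length L.
    """

    group_id: str
    ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (sequences x columns) array")
        if self.s_k < 1 or self.L < 1:
            raise ValueError(
                f"group {self.group_id!r}: need at least one sequence and one column"
            )
        if len(self.ids) != self.s_k:
            raise ValueError(f"group {self.group_id!r}: ids/codes row mismatch")

    @property
    def s_k(self) -> int:
        """Number of sequences in the group."""
        return self.codes.shape[0]

    @property
    def L(self) -> int:
        """Aligned length (columns)."""
        return self.codes.shape[1]

    @property
    def sequences(self) -> list[tuple[str, str]]:
        return [(sid, alphabet.decode(row)) for sid, row in zip(self.ids, self.codes)]

    @classmethod
    def from_strings(
        cls,
        group_id: str,
        records: Iterable[tuple[str, str]],
        *,
        nonstandard: str = "x",
        stop: str = "error",
    ) -> "GroupAlignment":
        ids: list[str] = []
        rows: list[np.ndarray] = []
        length: int | None = None
        for sid, seq in records:
            row = alphabet.encode(seq, nonstandard=nonstandard, stop=stop)
            if length is None:
                length = row.size
            elif row.size != length:
                raise RaggedAlignmentError(
                    f"record {group_id!r}, row {sid!r}: length {row.size} != {length}"
                )
            ids.append(sid)
            rows.append(row)
        if not ids:
            raise NoRecordsError(f"record {group_id!r}: no sequences")
        return cls(group_id, ids, np.vstack(rows))


# ---------------------------------------------------------------------------
# Stockholm / FASTA input


def _stockholm_record_meta(text: str) -> list[dict[str, object]]:
    """Light pre-scan of a Stockholm file: per-record GF ID/AC and row lengths.

    Used to attach group identifiers (Bio.AlignIO drops ``#=GF`` lines on some
    versions) and to name the offending record/row when the alignment is
    ragged.
    """
    records: list[dict[str, object]] = []
    current: dict[str, object] | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("# STOCKHOLM"):
            current = {"id": None, "rows": {}, "order": []}
            records.append(current)
            continue
        if current is None or not stripped or stripped == "//":
            continue
        if stripped.startswith("#=GF"):
            parts = stripped.split(None, 2)
            if len(parts) == 3 and parts[1] in ("ID", "AC") and current["id"] is None:
                current["id"] = parts[2]
            continue
        if stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        if len(parts) != 2:
            continue
        name, chunk = parts
        rows: dict[str, int] = current["rows"]  # type: ignore[assignment]
        if name not in rows:
            current["order"].append(name)  # type: ignore[union-attr]
        rows[name] = rows.get(name, 0) + len(chunk)
    return records


def _raise_if_ragged(meta: list[dict[str, object]]) -> None:
    for k, rec in enumerate(meta):
        rows: dict[str, int] = rec["rows"]  # type: ignore[assignment]
        order: list[str] = rec["order"]  # type: ignore[assignment]
        if not order:
            continue
        ref = rows[order[0]]
        for name in order[1:]:
            if rows[name] != ref:
                rid = rec["id"] or f"#{k}"
                raise RaggedAlignmentError(
                    f"record {rid!r}, row {name!r}: length {rows[name]} != {ref}"
                )


def read_stockholm(
    path: str | Path,
    *,
    nonstandard: str = "x",
    stop: str = "error",
) -> list[GroupAlignment]:
    """Read a (possibly multi-record) Stockholm 1.0 file into groups.

    ``.`` and ``-`` both become the gap symbol and lowercase insert-state
    letters are uppercased, so insert columns are treated as ordinary gapped
    columns (see the package methods note for the rationale and switch).
    """
    text = Path(path).read_text()
    meta = _stockholm_record_meta(text)
    if not meta:
        raise NoRecordsError(f"{path}: no Stockholm records")
    try:
        alignments = list(AlignIO.parse(io.StringIO(text), "stockholm"))
    except ValueError as exc:
        _raise_if_ragged(meta)  # produce the precise record/row if that is the cause
        raise RaggedAlignmentError(f"{path}: {exc}") from exc
    groups: list[GroupAlignment] = []
    for k, aln in enumerate(alignments):
        gid = (meta[k]["id"] if k < len(meta) else None) or f"record{k}"
        groups.append(
            GroupAlignment.from_strings(
                str(gid),
                ((rec.id, str(rec.seq)) for rec in aln),
                nonstandard=nonstandard,
                stop=stop,
            )
        )
    if not groups:
        raise NoRecordsError(f"{path}: no Stockholm records")
    return groups


def read_fasta_aligned(
    path: str | Path,
    *,
    group_id: str | None = None,
    nonstandard: str = "x",
    stop: str = "error",
) -> GroupAlignment:
    """Read one aligned-FASTA file as a single group (all rows equal length)."""
    from Bio import SeqIO

    gid = group_id or Path(path).stem
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise NoRecordsError(f"{path}: no records")
    return GroupAlignment.from_strings(
        gid, records, nonstandard=nonstandard, stop=stop
    )


def write_stockholm(groups: Iterable[GroupAlignment], path: str | Path) -> None:
    """Write groups as a multi-record Stockholm 1.0 file (round-trips through
    :func:`read_stockholm`)."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write("# STOCKHOLM 1.0\n")
            fh.write(f"#=GF ID {g.group_id}\n")
            width = max(len(sid) for sid in g.ids) + 2
            for sid, seq in g.sequences:
                fh.write(f"{sid:<{width}}{seq}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Matrix files


def write_matrix(
    m: SubstitutionMatrix,
    path: str | Path,
    alphabet_order: Sequence[str] | None = None,
    *,
    include_stop: bool = False,
    stop_score: int | None = None,
) -> None:
    """Write the integer score table in the standard search-tool dialect.

    ``alphabet_order`` selects and orders the emitted symbols (default: the
    full extended alphabet).  With ``include_stop`` a ``*`` row/column filled
    with ``stop_score`` (default: the matrix minimum) is appended, as many
    search tools expect.
    """
    order = tuple(alphabet_order or DEFAULT_ALPHABET_ORDER)
    missing = [s for s in order if s not in m.alphabet]
    if missing:
        raise MatrixFormatError(f"symbols absent from matrix: {missing}")
    idx = [m.alphabet.index(s) for s in order]
    table = m.scores_int[np.ix_(idx, idx)]
    floor = int(stop_score if stop_score is not None else table.min())
    width = max(3, max(len(str(int(v))) for v in table.ravel()) + 1)
    with open(path, "w") as fh:
        for line in m.header_comments():
            fh.write(f"# {line}\n")
        symbols = list(order) + ([alphabet.STOP] if include_stop else [])
        fh.write(" " + "".join(f"{s:>{width}}" for s in symbols) + "\n")
        for i, s in enumerate(order):
            row = [f"{int(v):>{width}}" for v in table[i]]
            if include_stop:
                row.append(f"{floor:>{width}}")
            fh.write(s + "".join(row) + "\n")
        if include_stop:
            row = [f"{floor:>{width}}"] * len(order) + [f"{1:>{width}}"]
            fh.write(alphabet.STOP + "".join(row) + "\n")


def read_matrix(path: str | Path, *, on_asymmetric: str = "warn") -> SubstitutionMatrix:
    """Parse a square matrix text file back into a :class:`SubstitutionMatrix`.

    ``on_asymmetric`` is one of ``"warn"`` (keep as read), ``"symmetrize"``
    (average the two triangles) or ``"error"``.
    """
    header: list[str] = []
    symbols: list[str] | None = None
    rows: dict[str, list[int]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            header.append(stripped.lstrip("#").strip())
            continue
        parts = stripped.split()
        if symbols is None:
            if any(len(p) != 1 for p in parts):
                raise MatrixFormatError(f"{path}:{lineno}: malformed header row")
            symbols = parts
            continue
        label = parts[0]
        if len(label) != 1 or label not in symbols:
            raise MatrixFormatError(
                f"{path}:{lineno}: missing or unknown row label {label!r}"
            )
        if len(parts) - 1 != len(symbols):
            raise MatrixFormatError(
                f"{path}:{lineno}: row {label!r} has {len(parts) - 1} entries, "
                f"expected {len(symbols)}"
            )
        try:
            values = [int(p) for p in parts[1:]]
        except ValueError as exc:
            raise MatrixFormatError(
                f"{path}:{lineno}: non-integer entry in row {label!r}"
            ) from exc
        rows[label] = values
        order.append(label)
    if symbols is None:
        raise MatrixFormatError(f"{path}: no header row found")
    missing = [s for s in symbols if s not in rows]
    if missing:
        raise MatrixFormatError(f"{path}: missing row(s) for label(s) {missing}")
    table = np.array([rows[s] for s in symbols], dtype=int)
    if not np.array_equal(table, table.T):
        if on_asymmetric == "error":
            raise MatrixFormatError(f"{path}: score table is not symmetric")
        warnings.warn(f"{path}: score table is not symmetric", stacklevel=2)
        if on_asymmetric == "symmetrize":
            table = (table + table.T) // 2
    meta: dict[str, str] = {}
    for line in header:
        if ":" in line:
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    from .logodds import SubstitutionMatrix

    return SubstitutionMatrix(
        alphabet=tuple(symbols),
        scores_int=table,
        scores_raw=None,
        meta=meta,
    )
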