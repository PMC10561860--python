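"""Sequences, secondary structures, and folding backends.

RNA sequences are handled as :class:`RnaRecord` objects (strict {A,C,G,U}
alphabet after normalization), secondary structures as :class:`SecondaryStructure`
objects carrying a dot-bracket string, minimum free energy (MFE, kcal/mol), a
1-based pair table and derived structural motifs (stems, hairpin loops, base
pairs).

Two folding backends implement the :class:`FoldingBackend` contract:

* :class:`ViennaBackend` — wraps the RNAfold thermodynamic model (MFE structure
  plus partition-function base-pair probabilities); imported lazily so the
  package is usable without the bindings.
* :class:`StackingBackend` — a deterministic base-pair-maximization folder with
  a crude stacking score, used for reproducible fixtures.

Conventions: positions are 1-based, intervals closed; dot-bracket uses the
plain alphabet {'(', ')', '.'} — pseudoknot alphabets are rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Protocol

import numpy as np

__all__ = [
    "RnaRecord",
    "SecondaryStructure",
    "FoldingBackend",
    "ViennaBackend",
    "StackingBackend",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "parse_vienna",
    "write_vienna",
    "build_pair_table",
    "annotate_motifs",
]

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick plus G·U wobble pairs.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class ParseError(ValueError):
    """Raised for malformed FASTA / Vienna / dot-bracket input."""


@dataclass(frozen=True)
class RnaRecord:
    """An identified RNA sequence.

    Attributes
    ----------
    id : str
        Sequence identifier (unique within a collection).
    sequence : str
        RNA string over {A, C, G, U}; length ``L`` in nucleotides.
    source : str
        Free-text provenance tag.
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("record id must be non-empty")
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-ACGU symbols {sorted(bad)} "
                "(ambiguity codes are rejected; normalize first)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase and apply DNA→RNA (T→U) normalization. No validation."""
    return raw.strip().upper().replace("T", "U")


@dataclass
class SecondaryStructure:
    """A secondary structure in dot-bracket notation with derived motifs.

    ``pair_table`` maps each paired 1-based position to its partner (symmetric
    and involutive). Motif fields follow the hairpin-classification
    conventions: a *stem* is a maximal run of stacked pairs of length >= the
    stem threshold (default 4, i.e. more than three contiguous base pairs); a
    *hairpin loop* is a maximal unpaired run immediately enclosed by a single
    pair; ``loop_length`` is the total number of unpaired bases across hairpin
    loops.
    """

    dotbracket: str
    mfe: float = 0.0
    pair_table: dict[int, int] = field(default_factory=dict)
    tot_bp: int = 0
    n_stems: int = 0
    n_loops: int = 0
    loop_length: int = 0
    pair_probs: np.ndarray | None = None  # upper-triangular (L, L), p_ij in [0,1]

    def __post_init__(self) -> None:
        bad = set(self.dotbracket) - set("().")
        if bad:
            raise ParseError(
                f"unsupported dot-bracket symbols {sorted(bad)} (pseudoknots rejected)"
            )
        if not self.pair_table:
            self.pair_table = build_pair_table(self.dotbracket)
        self.tot_bp = self.dotbracket.count("(")

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def hairpin_loops(self) -> list[tuple[int, int]]:
        """1-based closed intervals [start, end] of each hairpin loop, 5'→3'."""
        return _hairpin_loops(self.dotbracket, self.pair_table)


class FoldingBackend(Protocol):
    """Contract for obtaining structures, MFE and pair probabilities.

    Implementations must be deterministic for a fixed sequence and version,
    and ``fold`` must return a structure of exactly the sequence length.
    """

    def fold(self, sequence: str) -> SecondaryStructure: ...

    def pairing_probabilities(self, sequence: str) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# FASTA / Vienna I/O
# ---------------------------------------------------------------------------


def read_fasta(path, *, source: str = "", permissive: bool = False) -> list[RnaRecord]:
    """Read a FASTA file into :class:`RnaRecord` objects, order preserved.

    T→U and lowercase→uppercase normalization is applied at ingest. Records
    containing ambiguity codes (N, R, ...) raise :class:`ParseError` naming
    the offending entry; with ``permissive=True`` they are skipped with a
    warning instead.
    """
    from Bio import SeqIO

    records: list[RnaRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        seq = normalize_sequence(str(entry.seq))
        if not seq:
            raise ParseError(f"{path}: record {entry.id!r} has an empty sequence")
        if set(seq) - RNA_ALPHABET:
            if permissive:
                import warnings

                warnings.warn(
                    f"skipping record {entry.id!r}: ambiguity codes present",
                    stacklevel=2,
                )
                continue
            raise ParseError(
                f"{path}: record {entry.id!r} contains ambiguity codes "
                f"{sorted(set(seq) - RNA_ALPHABET)}"
            )
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(RnaRecord(id=entry.id, sequence=seq, source=source or str(path)))
    return records


def write_fasta(records: Iterable[RnaRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _iter_vienna_blocks(lines: Iterator[str]) -> Iterator[tuple[str, str, str]]:
    header = seq = None
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                raise ParseError(f"entry {header!r}: missing structure line")
            header = line[1:].strip()
        elif seq is None:
            if header is None:
                raise ParseError("Vienna input does not start with a '>' header")
            seq = line
        else:
            yield header, seq, line
            header = seq = None
    if header is not None:
        raise ParseError(f"entry {header!r}: truncated Vienna block")


def parse_vienna(path_or_text) -> list[tuple[RnaRecord, SecondaryStructure]]:
    """Parse Vienna/RNAfold output: ``>id`` / sequence / ``structure (mfe)``.

    The MFE is the trailing parenthesized signed decimal on the structure
    line, in kcal/mol. Enforces that the dot-bracket length equals the
    sequence length and that brackets balance.
    """
    import re

    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines: Iterator[str] = iter(io.StringIO(path_or_text))
    else:
        lines = iter(open(path_or_text))

    mfe_re = re.compile(r"^(?P<db>[().]+)\s*\(\s*(?P<mfe>-?\d+(?:\.\d+)?)\s*\)$")
    out: list[tuple[RnaRecord, SecondaryStructure]] = []
    for header, seq_raw, struct_line in _iter_vienna_blocks(lines):
        m = mfe_re.match(struct_line)
        if m is None:
            raise ParseError(
                f"entry {header!r}: structure line lacks a '(<mfe>)' suffix: "
                f"{struct_line!r}"
            )
        db, mfe = m.group("db"), float(m.group("mfe"))
        seq = normalize_sequence(seq_raw)
        if len(db) != len(seq):
            raise ParseError(
                f"entry {header!r}: structure length {len(db)} != sequence "
                f"length {len(seq)}"
            )
        rec = RnaRecord(id=header.split()[0], sequence=seq)
        structure = annotate_motifs(SecondaryStructure(dotbracket=db, mfe=mfe))
        out.append((rec, structure))
    return out


def write_vienna(pairs: Iterable[tuple[RnaRecord, SecondaryStructure]], path) -> None:
    """Write (record, structure) pairs in Vienna format, MFE to 2 decimals."""
    with open(path, "w") as fh:
        for rec, st in pairs:
            fh.write(f">{rec.id}\n{rec.sequence}\n{st.dotbracket} ({st.mfe:.2f})\n")


# ---------------------------------------------------------------------------
# Pair tables and motifs
# ---------------------------------------------------------------------------


def build_pair_table(dotbracket: str) -> dict[int, int]:
    """Stack-match a balanced dot-bracket string into a 1-based pair table.

    Unpaired positions are absent from the table. Raises :class:`ParseError`
    at the first offending index for unbalanced input.
    """
    table: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            opener = stack.pop()
            table[opener] = pos
            table[pos] = opener
        elif ch != ".":
            raise ParseError(f"unsupported symbol {ch!r} at position {pos}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[0]}")
    return table


def _stem_runs(pair_table: dict[int, int]) -> list[list[tuple[int, int]]]:
    """Maximal runs of stacked pairs [(i,j), (i+1,j-1), ...], 5'→3'."""
    openers = sorted(i for i, j in pair_table.items() if i < j)
    runs: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for i in openers:
        j = pair_table[i]
        if current and i == current[-1][0] + 1 and j == current[-1][1] - 1:
            current.append((i, j))
        else:
            if current:
                runs.append(current)
            current = [(i, j)]
    if current:
        runs.append(current)
    return runs


def _hairpin_loops(dotbracket: str, pair_table: dict[int, int]) -> list[tuple[int, int]]:
    """Unpaired runs immediately enclosed by a single pair: ``(\\.+)`` motifs."""
    loops: list[tuple[int, int]] = []
    n = len(dotbracket)
    for i, ch in enumerate(dotbracket, start=1):
        if ch != "(":
            continue
        # walk the dots following the opener; a loop needs ")" right after
        k = i + 1
        while k <= n and dotbracket[k - 1] == ".":
            k += 1
        if k > i + 1 and k <= n and dotbracket[k - 1] == ")" and pair_table.get(i) == k:
            loops.append((i + 1, k - 1))
    return loops


def annotate_motifs(structure: SecondaryStructure, *, min_stem: int = 4) -> SecondaryStructure:
    """Populate stem/loop/base-pair counts on a structure, in place.

    ``min_stem`` is the minimum stacked-run length counted as a stem; the
    default 4 reads "more than three contiguous base pairs" literally, and can
    be lowered to 3 for comparison with tools that use that convention.
    """
    runs = _stem_runs(structure.pair_table)
    loops = _hairpin_loops(structure.dotbracket, structure.pair_table)
    structure.n_stems = sum(1 for run in runs if len(run) >= min_stem)
    structure.n_loops = len(loops)
    structure.loop_length = sum(end - start + 1 for start, end in loops)
    structure.tot_bp = structure.dotbracket.count("(")
    return structure


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class ViennaBackend:
    """Thermodynamic folding through the ViennaRNA (RNAfold) bindings.

    ``fold`` returns the MFE structure; ``pairing_probabilities`` runs the
    partition function and returns the base-pair probability matrix.
    """

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - env without bindings
            raise ImportError(
                "ViennaBackend requires the ViennaRNA python bindings "
                "(`import RNA`); use StackingBackend or supply fixture "
                "structures instead"
            ) from exc
        self._rna = __import__("RNA")

    def fold(self, sequence: str) -> SecondaryStructure:
        db, mfe = self._rna.fold(sequence)
        return annotate_motifs(SecondaryStructure(dotbracket=db, mfe=float(mfe)))

    def pairing_probabilities(self, sequence: str) -> np.ndarray:
        fc = self._rna.fold_compound(sequence)
        fc.pf()
        bpp = np.array(fc.bpp())  # 1-based (L+1, L+1)
        return np.triu(bpp[1:, 1:], k=1)


class StackingBackend:
    """Deterministic base-pair-maximization folder with a stacking score.

    A Nussinov-style dynamic program maximizes a score of +1 per canonical
    pair (A·U, G·C, G·U) with a +1 bonus per stacked pair, minimum hairpin
    loop of 3 nt. The reported "MFE" is a crude surrogate energy:
    -2 kcal/mol per stacked pair, +3 kcal/mol per hairpin loop. Not
    thermodynamically accurate — it exists to give fixtures a consistent,
    reproducible structure and a plausibly scaled negative energy without a
    folding engine.

    ``pairing_probabilities`` returns ``pair_confidence`` (default 0.9) on
    each predicted pair: a sharp, deterministic pseudo-ensemble.
    """

    MIN_LOOP = 3

    def __init__(self, pair_confidence: float = 0.9) -> None:
        if not 0.0 < pair_confidence <= 1.0:
            raise ValueError("pair_confidence must be in (0, 1]")
        self.pair_confidence = pair_confidence

    @staticmethod
    def _can_pair(a: str, b: str) -> bool:
        return (a, b) in CANONICAL_PAIRS

    def fold(self, sequence: str) -> SecondaryStructure:
        n = len(sequence)
        if n == 0:
            raise ValueError("cannot fold an empty sequence")
        # score[i][j]: best score on sequence[i..j] (0-based inclusive)
        score = [[0] * n for _ in range(n)]
        pair_here = [[False] * n for _ in range(n)]
        for span in range(self.MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = score[i][j - 1]  # j unpaired
                paired = -1
                if self._can_pair(sequence[i], sequence[j]):
                    inner = score[i + 1][j - 1] if j - 1 >= i + 1 else 0
                    bonus = 2 if (j - i > self.MIN_LOOP + 2 and pair_here[i + 1][j - 1]) else 1
                    paired = inner + bonus
                    if paired > best:
                        best = paired
                # bifurcation: j pairs with some k in (i, j)
                for k in range(i + 1, j):
                    if self._can_pair(sequence[k], sequence[j]):
                        cand = score[i][k - 1] + score[k][j]
                        if cand > best:
                            best = cand
                score[i][j] = best
                pair_here[i][j] = paired == best and paired >= 0
        db = ["."] * n
        self._traceback(sequence, score, pair_here, 0, n - 1, db)
        structure = annotate_motifs(SecondaryStructure(dotbracket="".join(db)))
        structure.mfe = self._surrogate_energy(structure)
        return structure

    def _traceback(self, seq, score, pair_here, i, j, db) -> None:
        while i < j:
            if score[i][j] == 0:
                return
            if pair_here[i][j]:
                db[i], db[j] = "(", ")"
                i, j = i + 1, j - 1
                continue
            if score[i][j] == score[i][j - 1]:
                j -= 1
                continue
            for k in range(i + 1, j):
                if (
                    self._can_pair(seq[k], seq[j])
                    and score[i][j] == score[i][k - 1] + score[k][j]
                ):
                    self._traceback(seq, score, pair_here, k, j, db)
                    j = k - 1
                    break
            else:  # pragma: no cover - defensive
                return

    @staticmethod
    def _surrogate_energy(structure: SecondaryStructure) -> float:
        runs = _stem_runs(structure.pair_table)
        stacked = sum(len(run) - 1 for run in runs)
        loops = len(_hairpin_loops(structure.dotbracket, structure.pair_table))
        return float(-2 * stacked + 3 * loops)

    def pairing_probabilities(self, sequence: str) -> np.ndarray:
        st = self.fold(sequence)
        n = len(sequence)
        probs = np.zeros((n, n))
        for i, j in st.pair_table.items():
            if i < j:
                probs[i - 1, j - 1] = self.pair_confidence
        return probs


def fold_with_probabilities(
    backend: FoldingBackend, sequence: str
) -> SecondaryStructure:
    """Fold and attach the backend's pair-probability matrix."""
    st = backend.fold(sequence)
    st.pair_probs = backend.pairing_probabilities(sequence)
    return st
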