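"""Sequence, annotation, PSSM and disorder I/O plus window assembly.

All user-facing coordinates are 1-based and inclusive.  Windows overhanging a
sequence end are padded with ``'X'``, which every encoder treats as inert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Padding / unknown-residue symbol.
PAD = "X"
_ALLOWED = set(AMINO_ACIDS) | {PAD}

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 amino acids plus ``'X'``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def lysine_positions(self) -> list[int]:
        """1-based positions of every lysine in the sequence."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]


@dataclass(frozen=True)
class SiteAnnotation:
    """One labeled lysine: ``(protein_id, 1-based position, label)``."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length, lysine-centered slice of a protein.

    ``residues`` has odd length ``w`` with the lysine at window site
    ``(w + 1) // 2`` (site 11 for the default w=21); sites are 1-based.
    """

    protein_id: str
    center: int
    residues: str
    label: str

    def __post_init__(self) -> None:
        w = len(self.residues)
        if w % 2 == 0:
            raise ValueError("window size must be odd")
        if self.residues[w // 2] != "K":
            raise ValueError("window center must be a lysine")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def w(self) -> int:
        return len(self.residues)

    @property
    def center_site(self) -> int:
        """1-based window site of the central lysine: (w+1)/2."""
        return (self.w + 1) // 2

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass
class PssmMatrix:
    """Per-protein position-specific scoring matrix (PSI-BLAST log-odds).

    ``raw`` holds the integer log-odds as parsed; ``normalized`` is min-max
    scaled to [0, 1] over the whole matrix.  Columns follow :data:`AMINO_ACIDS`.
    """

    protein_id: str
    raw: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != 20:
            raise ValueError("PSSM must be an L x 20 matrix")
        self.normalized = normalize_pssm(self.raw, protein_id=self.protein_id)

    @property
    def length(self) -> int:
        return self.raw.shape[0]


def normalize_pssm(raw: np.ndarray, protein_id: str = "?") -> np.ndarray:
    """Min-max normalize a whole PSSM to [0, 1]: (v - min) / (max - min).

    A constant matrix (max == min) maps to all 0.5 with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("PSSM for %s is constant; normalized set to 0.5", protein_id)
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


@dataclass
class DisorderTrack:
    """Per-residue intrinsic-disorder scores, clamped to [0, 1]."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.clip(np.asarray(self.scores, dtype=float), 0.0, 1.0)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise ValueError("disorder track must be a non-empty 1-D vector")

    @property
    def length(self) -> int:
        return self.scores.size


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased.  Records containing letters outside the
    20-amino-acid + ``'X'`` alphabet are skipped with a warning.  An empty
    file raises ``ValueError("no sequences")``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED
        if bad or not seq:
            logger.warning(
                "skipping %s: illegal residues %s", rec.id, sorted(bad) or "<empty>"
            )
            continue
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if n_seen == 0:
        raise ValueError(f"no sequences in {path}")
    return records


def read_annotations(
    path: str | Path, proteins: Iterable[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read a TSV site table (protein_id, position, label) and validate it.

    Rows referencing unknown proteins, non-lysine positions or malformed
    fields are skipped with a warning.  Duplicate (protein, position) rows:
    last one wins, with a warning.
    """
    by_id = {p.id: p for p in proteins}
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    accepted: dict[tuple[str, int], SiteAnnotation] = {}
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        try:
            pos = int(row.position)
            label = str(row.label).strip().lower()
            ann = SiteAnnotation(protein_id=pid, position=pos, label=label)
        except (TypeError, ValueError) as exc:
            logger.warning("malformed annotation row %r skipped: %s", tuple(row), exc)
            continue
        prot = by_id.get(pid)
        if prot is None:
            logger.warning("unknown protein %r in annotations; row skipped", pid)
            continue
        if not (1 <= pos <= prot.length) or prot.sequence[pos - 1] != "K":
            logger.warning(
                "annotation %s:%d rejected: position is not a lysine", pid, pos
            )
            continue
        if (pid, pos) in accepted:
            logger.warning("duplicate annotation %s:%d; last row wins", pid, pos)
        accepted[(pid, pos)] = ann
    return list(accepted.values())


def derive_negative_sites(
    proteins: Iterable[ProteinRecord], positives: Iterable[SiteAnnotation]
) -> list[SiteAnnotation]:
    """Every lysine not annotated as positive becomes a negative site."""
    pos_keys = {(a.protein_id, a.position) for a in positives}
    negatives = []
    for prot in proteins:
        for pos in prot.lysine_positions():
            if (prot.id, pos) not in pos_keys:
                negatives.append(
                    SiteAnnotation(protein_id=prot.id, position=pos, label=NEGATIVE)
                )
    return negatives


def extract_window(
    protein: ProteinRecord, position: int, w: int = 21, label: str = NEGATIVE
) -> PeptideWindow:
    """Slice the w residues centered on a lysine, padding ends with 'X'."""
    if w % 2 == 0:
        raise ValueError("window size must be odd")
    if not (1 <= position <= protein.length) or protein.sequence[position - 1] != "K":
        raise ValueError(
            f"{protein.id}:{position} is not a lysine; cannot center a window"
        )
    half = (w - 1) // 2
    chars = []
    for p in range(position - half, position + half + 1):
        if 1 <= p <= protein.length:
            chars.append(protein.sequence[p - 1])
        else:
            chars.append(PAD)
    return PeptideWindow(
        protein_id=protein.id, center=position, residues="".join(chars), label=label
    )


def build_windows(
    proteins: Iterable[ProteinRecord],
    annotations: Iterable[SiteAnnotation],
    w: int = 21,
) -> list[PeptideWindow]:
    """Extract one window per annotated site, in input order."""
    by_id = {p.id: p for p in proteins}
    return [
        extract_window(by_id[a.protein_id], a.position, w=w, label=a.label)
        for a in annotations
    ]


# ---------------------------------------------------------------------------
# PSSM / disorder files
# ---------------------------------------------------------------------------

def read_pssm(
    path: str | Path,
    protein_id: str | None = None,
    expected_length: int | None = None,
) -> PssmMatrix:
    """Parse a PSI-BLAST ASCII matrix file (the ``-Q`` output dialect).

    The first 20 numeric columns of each residue row are the log-odds
    scores; the trailing percentage block, if present, is ignored.  Columns
    are re-ordered from the file's header to the canonical alphabet.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    column_order: list[str] | None = None
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if column_order is None:
                # header: 40 (or 20) single-letter amino-acid columns
                if len(fields) >= 20 and all(
                    f in _ALLOWED and len(f) == 1 for f in fields[:20]
                ):
                    column_order = fields[:20]
                continue
            # data row: index, residue letter, >= 20 integers
            if len(fields) >= 22 and fields[0].isdigit() and len(fields[1]) == 1:
                try:
                    rows.append([int(v) for v in fields[2:22]])
                except ValueError:
                    continue
    if column_order is None or not rows:
        raise ValueError(f"{path} is not a recognizable PSI-BLAST ASCII matrix")
    raw = np.array(rows, dtype=float)
    # re-order columns to A, C, D, ..., Y
    order = [column_order.index(aa) for aa in AMINO_ACIDS]
    raw = raw[:, order]
    if expected_length is not None and raw.shape[0] != expected_length:
        raise ValueError(
            f"{path}: {raw.shape[0]} PSSM rows but sequence length {expected_length}"
        )
    return PssmMatrix(protein_id=protein_id, raw=raw)


def read_disorder(
    path: str | Path,
    protein_id: str | None = None,
    expected_length: int | None = None,
) -> DisorderTrack:
    """Read a per-protein disorder TSV with columns (position, score)."""
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    df = pd.read_csv(path, sep="\t")
    if not {"position", "score"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns position, score")
    df = df.sort_values("position")
    positions = df["position"].to_numpy(dtype=int)
    if not np.array_equal(positions, np.arange(1, positions.size + 1)):
        raise ValueError(f"{path}: positions must be contiguous starting at 1")
    if expected_length is not None and positions.size != expected_length:
        raise ValueError(
            f"{path}: {positions.size} scores but sequence length {expected_length}"
        )
    return DisorderTrack(protein_id=protein_id, scores=df["score"].to_numpy(float))


class TrackProvider:
    """Supplies PSSM matrices and disorder tracks per protein id.

    Backed either by in-memory mappings or by a directory holding
    ``<protein_id>.pssm`` and ``<protein_id>.disorder.tsv`` files.
    """

    def __init__(
        self,
        pssms: Mapping[str, PssmMatrix] | None = None,
        disorder: Mapping[str, DisorderTrack] | None = None,
        directory: str | Path | None = None,
    ) -> None:
        self._pssms = dict(pssms or {})
        self._disorder = dict(disorder or {})
        self._dir = Path(directory) if directory is not None else None

    def get_pssm(self, protein_id: str) -> PssmMatrix:
        if protein_id not in self._pssms:
            if self._dir is None:
                raise KeyError(f"no PSSM available for protein {protein_id!r}")
            f = self._dir / f"{protein_id}.pssm"
            if not f.exists():
                raise KeyError(f"no PSSM file for protein {protein_id!r} ({f})")
            self._pssms[protein_id] = read_pssm(f, protein_id=protein_id)
        return self._pssms[protein_id]

    def get_disorder(self, protein_id: str) -> DisorderTrack:
        if protein_id not in self._disorder:
            if self._dir is None:
                raise KeyError(f"no disorder track for protein {protein_id!r}")
            f = self._dir / f"{protein_id}.disorder.tsv"
            if not f.exists():
                raise KeyError(f"no disorder file for protein {protein_id!r} ({f})")
            self._disorder[protein_id] = read_disorder(f, protein_id=protein_id)
        return self._disorder[protein_id]


# ---------------------------------------------------------------------------
# splits and serialization
# ---------------------------------------------------------------------------

def split_by_protein(
    windows: Sequence[PeptideWindow], test_fraction: float, seed: int
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Protein-level train/test split: all windows of a protein stay together."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    protein_ids = sorted({wdw.protein_id for wdw in windows})
    if len(protein_ids) < 2:
        raise ValueError("need at least 2 proteins to split")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(protein_ids))
    n_test = min(max(1, round(len(protein_ids) * test_fraction)), len(protein_ids) - 1)
    test_ids = set(shuffled[:n_test])
    train = [wdw for wdw in windows if wdw.protein_id not in test_ids]
    test = [wdw for wdw in windows if wdw.protein_id in test_ids]
    return train, test


def windows_to_frame(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [w.protein_id for w in windows],
            "position": [w.center for w in windows],
            "residues": [w.residues for w in windows],
            "label": [w.label for w in windows],
        }
    )


def write_windows(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)
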