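"""Sequence windows, one-hot encoding, dataset construction and I/O.

A training instance pairs two 100-nt windows around the back-splice
junction: the splice-acceptor (SA) window, laid out as 50 nt of upstream
intron followed by 50 nt of exon, and the splice-donor (SD) window, laid
out as 50 nt of exon followed by 50 nt of downstream intron.  All
sequences are canonical RNA (uppercase, U not T); the splice boundary
sits between window indices 49 and 50 (0-based, half-open coordinates).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

from .errors import (
    FlankTooShort,
    InfeasibleSplit,
    InvalidAlphabet,
    LengthMismatch,
    ParseError,
)

WINDOW_LEN = 100
FLANK_LEN = 50
#: index of the first nucleotide 3' of the splice site within a window
BOUNDARY_INDEX = 50
ALPHABET = "ACGU"
_CANON = str.maketrans("acgtunT", "ACGUUNU")
_VALID = set("ACGTUNacgtun")
_CHANNEL = {b: i for i, b in enumerate(ALPHABET)}

#: maximum tolerated fraction of N per window at load time
MAX_N_FRACTION = 0.10


@dataclasses.dataclass(frozen=True)
class SamplePair:
    """One labeled instance: an SA window and an SD window of 100 nt each."""

    id: str
    sa_seq: str
    sd_seq: str
    label: int
    species: str | None = None

    def __post_init__(self):
        for name, seq in (("sa_seq", self.sa_seq), ("sd_seq", self.sd_seq)):
            if len(seq) != WINDOW_LEN:
                raise LengthMismatch(
                    f"{name} of {self.id!r} has length {len(seq)}, expected {WINDOW_LEN}"
                )
            if not set(seq) <= set(ALPHABET + "N"):
                bad = sorted(set(seq) - set(ALPHABET + "N"))
                raise InvalidAlphabet(bad[0], seq.index(bad[0]))
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclasses.dataclass(frozen=True)
class SiteWindow:
    """A single 100-nt window with its intron/exon layout.

    SA windows run intron (positions 0-49) then exon (50-99); SD windows
    run exon then intron.
    """

    site_kind: str  # "SA" or "SD"
    sequence: str
    boundary_index: int = BOUNDARY_INDEX

    def side_of(self, position: int) -> str:
        """Side ('intron' or 'exon') of a window position under this layout."""
        left = position < self.boundary_index
        if self.site_kind == "SA":
            return "intron" if left else "exon"
        return "exon" if left else "intron"


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    k: int
    assignments: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]


@dataclasses.dataclass(frozen=True)
class Transcript:
    """Simplified exon/intron structure used by the negative sampler.

    ``exons`` and ``introns`` are ordered 5'->3'; ``len(introns)`` must be
    ``len(exons) - 1``.
    """

    id: str
    exons: tuple[str, ...]
    introns: tuple[str, ...]

    def __post_init__(self):
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"transcript {self.id!r}: {len(self.exons)} exons require "
                f"{len(self.exons) - 1} introns, got {len(self.introns)}"
            )


def canonicalize(seq: str) -> str:
    """Uppercase a nucleotide string and map T to U.

    Raises :class:`InvalidAlphabet` naming the first offending position if
    a character outside {A,C,G,T,U,N} (either case) occurs.
    """
    if not seq:
        raise InvalidAlphabet("", 0)
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise InvalidAlphabet(c, i)
    return seq.translate(_CANON)


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a canonical 100-nt RNA string as a 100x4 {0,1} matrix.

    Channel order is (A, C, G, U); N rows are all zero.
    """
    if len(seq) != WINDOW_LEN:
        raise LengthMismatch(f"expected {WINDOW_LEN} nt, got {len(seq)}")
    mat = np.zeros((WINDOW_LEN, 4), dtype=np.float32)
    for i, c in enumerate(seq):
        j = _CHANNEL.get(c)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for N-free sequences."""
    out = []
    for row in np.asarray(mat):
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(ALPHABET[int(np.argmax(row))])
    return "".join(out)


def encode_pairs(pairs: Sequence[SamplePair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorize a dataset: (SA tensor, SD tensor, label vector)."""
    xa = np.stack([one_hot_encode(p.sa_seq) for p in pairs])
    xd = np.stack([one_hot_encode(p.sd_seq) for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.float32)
    return xa, xd, y


def build_window(intron_flank: str, exon_flank: str, site_kind: str) -> SiteWindow:
    """Assemble a 100-nt window from the two flanks of a splice site.

    Each flank is trimmed to the 50 nt proximal to the site.  Flanks
    shorter than 50 nt disqualify the site (:class:`FlankTooShort`),
    mirroring the dataset filter.
    """
    if site_kind not in ("SA", "SD"):
        raise ValueError(f"site_kind must be 'SA' or 'SD', got {site_kind!r}")
    if len(intron_flank) < FLANK_LEN or len(exon_flank) < FLANK_LEN:
        raise FlankTooShort(
            f"flanks of {len(intron_flank)} and {len(exon_flank)} nt; "
            f"both must be >= {FLANK_LEN}"
        )
    if site_kind == "SA":
        # intron ends at the acceptor; exon starts there
        seq = intron_flank[-FLANK_LEN:] + exon_flank[:FLANK_LEN]
    else:
        # exon ends at the donor; intron starts there
        seq = exon_flank[-FLANK_LEN:] + intron_flank[:FLANK_LEN]
    return SiteWindow(site_kind=site_kind, sequence=seq)


def deduplicate(pairs: Iterable[SamplePair]) -> list[SamplePair]:
    """Drop exact (sa_seq, sd_seq) duplicates, keeping first occurrences."""
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        key = (p.sa_seq, p.sd_seq)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def donor_acceptor_windows(tx: Transcript, donor_exon: int, acceptor_exon: int):
    """SA/SD windows for the junction joining ``donor_exon`` to ``acceptor_exon``.

    The donor site lies at the 3' end of ``exons[donor_exon]``; the acceptor
    at the 5' end of ``exons[acceptor_exon]``.  Raises FlankTooShort when a
    flank fails the 50-nt filter.
    """
    sd = build_window(
        intron_flank=tx.introns[donor_exon],
        exon_flank=tx.exons[donor_exon],
        site_kind="SD",
    )
    sa = build_window(
        intron_flank=tx.introns[acceptor_exon - 1],
        exon_flank=tx.exons[acceptor_exon],
        site_kind="SA",
    )
    return sa, sd


def sample_negatives(
    transcripts: Sequence[Transcript],
    positives: set[tuple[str, int, int]],
    n: int,
    seed: int,
) -> list[SamplePair]:
    """Draw negative window pairs from canonical splice sites.

    Each candidate pairs the donor of exon ``i`` with the acceptor of exon
    ``i+1`` or ``i+2`` of the same transcript (a junction covering two or
    three exons).  Candidates whose (transcript, donor exon, acceptor exon)
    coordinates appear in ``positives`` are rejected, as are candidates with
    a flank under 50 nt.  Sampling is uniform without replacement and
    deterministic for a fixed seed; if fewer than ``n`` candidates exist,
    all of them are returned.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    eligible: list[tuple[str, int, int, SiteWindow, SiteWindow]] = []
    for tx in transcripts:
        for i in range(len(tx.exons) - 1):
            for j in (i + 1, i + 2):
                if j >= len(tx.exons):
                    continue
                if (tx.id, i, j) in positives:
                    continue
                try:
                    sa, sd = donor_acceptor_windows(tx, i, j)
                except FlankTooShort:
                    continue
                eligible.append((tx.id, i, j, sa, sd))
    rng = np.random.default_rng(seed)
    take = min(n, len(eligible))
    idx = rng.choice(len(eligible), size=take, replace=False) if eligible else []
    out = []
    for r in sorted(int(i) for i in np.atleast_1d(idx)):
        tx_id, i, j, sa, sd = eligible[r]
        out.append(
            SamplePair(
                id=f"{tx_id}:d{i}a{j}",
                sa_seq=sa.sequence,
                sd_seq=sd.sequence,
                label=0,
            )
        )
    return out


def kfold_split(pairs: Sequence[SamplePair], k: int, seed: int) -> FoldSplit:
    """Stratified k-fold assignment of sample ids, deterministic per seed."""
    if k < 2:
        raise InfeasibleSplit(f"k must be >= 2, got {k}")
    labels = np.array([p.label for p in pairs])
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise InfeasibleSplit(
                f"class {cls} has {(labels == cls).sum()} members, fewer than k={k}"
            )
    # sort by id for input-order invariance, then let sklearn stratify
    order = np.argsort([p.id for p in pairs], kind="stable")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(order, labels[order])):
        for t in test_idx:
            assignments[pairs[order[t]].id] = fold
    return FoldSplit(k=k, assignments=assignments)


# ---------------------------------------------------------------------------
# dataset I/O

_TSV_COLUMNS = ["id", "sa_seq", "sd_seq", "label"]


def write_dataset(pairs: Sequence[SamplePair], path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            [(p.id, p.sa_seq, p.sd_seq, p.label) for p in pairs], columns=_TSV_COLUMNS
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "paired_fasta":
        _write_paired_fasta(pairs, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str | Path, format: str = "tsv") -> list[SamplePair]:
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "paired_fasta":
        return _read_paired_fasta(path)
    if format == "xlsx_sheets":
        return _read_xlsx_sheets(path)
    raise ValueError(f"unknown format {format!r}")


def _make_pair(id_, sa, sd, label, record: int, species: str | None = None) -> SamplePair:
    try:
        sa = canonicalize(str(sa))
        sd = canonicalize(str(sd))
        n_frac = max(sa.count("N") / len(sa), sd.count("N") / len(sd))
        if n_frac > MAX_N_FRACTION:
            raise ParseError(f"sample {id_!r} has >{MAX_N_FRACTION:.0%} N", record)
        return SamplePair(id=str(id_), sa_seq=sa, sd_seq=sd, label=int(label), species=species)
    except ParseError:
        raise
    except Exception as e:  # noqa: BLE001 - rewrap with record number
        raise ParseError(str(e), record) from e


def _read_tsv(path: Path) -> list[SamplePair]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"cannot read {path}: {e}") from e
    if list(df.columns) != _TSV_COLUMNS:
        raise ParseError(f"expected columns {_TSV_COLUMNS}, got {list(df.columns)}")
    return [
        _make_pair(r.id, r.sa_seq, r.sd_seq, r.label, record=i + 1)
        for i, r in enumerate(df.itertuples(index=False))
    ]


def _paired_fasta_paths(prefix: Path) -> tuple[Path, Path, Path]:
    base = str(prefix)
    return Path(base + "_sa.fasta"), Path(base + "_sd.fasta"), Path(base + "_labels.tsv")


def _write_paired_fasta(pairs: Sequence[SamplePair], prefix: Path) -> None:
    sa_path, sd_path, lab_path = _paired_fasta_paths(prefix)
    SeqIO.write(
        (SeqRecord(Seq(p.sa_seq), id=p.id, description="") for p in pairs), sa_path, "fasta"
    )
    SeqIO.write(
        (SeqRecord(Seq(p.sd_seq), id=p.id, description="") for p in pairs), sd_path, "fasta"
    )
    pd.DataFrame([(p.id, p.label) for p in pairs], columns=["id", "label"]).to_csv(
        lab_path, sep="\t", index=False
    )


def _read_paired_fasta(prefix: Path) -> list[SamplePair]:
    sa_path, sd_path, lab_path = _paired_fasta_paths(prefix)
    for p in (sa_path, sd_path, lab_path):
        if not p.exists():
            raise ParseError(f"missing paired-FASTA component {p}")
    sa = {r.id: str(r.seq) for r in SeqIO.parse(str(sa_path), "fasta")}
    sd = {r.id: str(r.seq) for r in SeqIO.parse(str(sd_path), "fasta")}
    if set(sa) != set(sd):
        odd = sorted(set(sa) ^ set(sd))
        raise ParseError(f"SA/SD id sets differ, e.g. {odd[:3]}")
    labels = pd.read_csv(lab_path, sep="\t", dtype=str)
    if list(labels.columns) != ["id", "label"]:
        raise ParseError(f"labels file must have columns ['id','label'], got {list(labels.columns)}")
    if set(labels["id"]) != set(sa):
        raise ParseError("label id set differs from FASTA id set")
    return [
        _make_pair(r.id, sa[r.id], sd[r.id], r.label, record=i + 1)
        for i, r in enumerate(labels.itertuples(index=False))
    ]


def _read_xlsx_sheets(path: Path) -> list[SamplePair]:
    """Import the supplementary-table layout: one sheet per species x label.

    Sheet names end in ``_positive`` / ``_negative``; each sheet carries SA
    and SD sequence columns (first two string columns are used).
    """
    try:
        book = pd.read_excel(path, sheet_name=None, dtype=str)
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"cannot read {path}: {e}") from e
    out: list[SamplePair] = []
    for sheet, df in book.items():
        low = sheet.strip().lower()
        if low.endswith("_positive"):
            label, species = 1, low[: -len("_positive")]
        elif low.endswith("_negative"):
            label, species = 0, low[: -len("_negative")]
        else:
            continue
        cols = list(df.columns)
        if len(cols) < 2:
            raise ParseError(f"sheet {sheet!r} needs at least two sequence columns")
        for i in range(len(df)):
            out.append(
                _make_pair(
                    f"{sheet}:{i}", df.iloc[i, 0], df.iloc[i, 1], label,
                    record=i + 1, species=species,
                )
            )
    return out
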