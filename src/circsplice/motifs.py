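"""From first-layer filters to motifs: PPMs, MEME export, positional analysis.

The first convolution layer scores every window position with every
filter (the candidate-motif evaluation matrix).  For each filter, the
best-scoring subsequence of each positive sample is collected and the
per-position nucleotide frequencies of those subsequences form a
position probability matrix (PPM).  PPMs are exported in MEME minimal
motif format for external comparison tools, and occurrence positions
support density profiles around the splice site, intron/exon enrichment
and cross-set PPM matching.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NoOccurrences, NoSupport
from .model import TrainedModel, first_layer_activations
from .seqdata import ALPHABET, BOUNDARY_INDEX, SamplePair

_MEME_VERSION_LINE = "MEME version 4"


@dataclasses.dataclass(frozen=True)
class PPM:
    """Position probability matrix over (A,C,G,U) for one filter."""

    matrix: np.ndarray  # L x 4, rows sum to 1
    filter_index: int = -1
    branch: str = ""
    support: int = 1
    name: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PPM matrix must be L x 4")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PPM rows must be non-negative and sum to 1")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.matrix, axis=1))

    def label(self) -> str:
        if self.name:
            return self.name
        br = f"{self.branch}_" if self.branch else ""
        return f"{br}filter{self.filter_index}"


@dataclasses.dataclass(frozen=True)
class MotifOccurrence:
    filter_index: int
    branch: str
    seq_id: str
    label: int
    start: int
    side: str
    score: float


def _branch_sequences(pairs: Sequence[SamplePair], branch: str) -> list[str]:
    branch = branch.lower()
    return [p.sa_seq if branch == "sa" else p.sd_seq for p in pairs]


def _side_of(branch: str, start: int, width: int) -> str:
    """Intron/exon side of an occurrence, decided by its window center.

    SA windows are intron (0-49) then exon; SD windows exon then intron.
    """
    center = start + width // 2
    left = center < BOUNDARY_INDEX
    if branch.lower() == "sa":
        return "intron" if left else "exon"
    return "exon" if left else "intron"


def select_subsequences(
    model: TrainedModel,
    pairs: Sequence[SamplePair],
    branch: str,
    positives_only: bool = True,
) -> dict[int, list[str]]:
    """Per filter, the argmax-scoring L-mer of each (positive) sequence.

    A sequence contributes its single best window per filter, and only if
    the post-ReLU score there is strictly positive; ties break to the
    leftmost position; L-mers containing N are skipped.
    """
    use = [p for p in pairs if p.label == 1] if positives_only else list(pairs)
    width = model.config.conv1_size
    out: dict[int, list[str]] = {k: [] for k in range(model.config.conv1_kernels)}
    if not use:
        return out
    acts = first_layer_activations(model, use, branch)  # (n, P, K)
    seqs = _branch_sequences(use, branch)
    best_pos = acts.argmax(axis=1)  # leftmost max (argmax tie rule)
    best_score = acts.max(axis=1)
    for i, seq in enumerate(seqs):
        for k in range(acts.shape[2]):
            if best_score[i, k] <= 0.0:
                continue
            s = int(best_pos[i, k])
            sub = seq[s : s + width]
            if "N" in sub:
                continue
            out[k].append(sub)
    return out


def cmem_to_ppm(
    subsequences: Sequence[str],
    filter_index: int = -1,
    branch: str = "",
) -> PPM:
    """Counting formula: entry (i, b) = count of base b at i / #subsequences."""
    if not subsequences:
        raise NoSupport("no qualifying subsequences for this filter")
    width = len(subsequences[0])
    if any(len(s) != width for s in subsequences):
        raise ValueError("subsequences must share one length")
    counts = np.zeros((width, 4))
    for s in subsequences:
        for i, c in enumerate(s):
            counts[i, ALPHABET.index(c)] += 1
    return PPM(
        matrix=counts / len(subsequences),
        filter_index=filter_index,
        branch=branch,
        support=len(subsequences),
    )


def extract_ppms(
    model: TrainedModel,
    pairs: Sequence[SamplePair],
    branch: str,
    positives_only: bool = True,
    trim: bool = False,
) -> list[PPM]:
    """PPMs for every filter with at least one qualifying subsequence."""
    subs = select_subsequences(model, pairs, branch, positives_only=positives_only)
    ppms = []
    for k in sorted(subs):
        if not subs[k]:
            continue
        ppm = cmem_to_ppm(subs[k], filter_index=k, branch=branch.lower())
        if trim:
            ppm = trim_low_information(ppm)
        ppms.append(ppm)
    return ppms


def information_content(ppm: PPM) -> np.ndarray:
    """Per-column information content in bits (uniform background)."""
    m = np.clip(ppm.matrix, 1e-12, 1.0)
    return 2.0 + np.sum(m * np.log2(m), axis=1)


def trim_low_information(ppm: PPM, min_bits: float = 0.1) -> PPM:
    """Strip uninformative flanking columns (< min_bits) from both ends."""
    ic = information_content(ppm)
    keep = np.where(ic >= min_bits)[0]
    if len(keep) == 0:
        return ppm
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    if (lo, hi) == (0, ppm.width):
        return ppm
    return dataclasses.replace(ppm, matrix=ppm.matrix[lo:hi])


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(
    ppms: Sequence[PPM],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    smoothing: float = 0.0,
) -> None:
    """Write motifs in MEME minimal format (RNA alphabet, no strand line).

    ``smoothing`` optionally mixes in a tiny uniform pseudo-probability
    for tools that reject exact zeros; it is off by default so the file
    reproduces the PPMs exactly.
    """
    lines = [_MEME_VERSION_LINE, "", "ALPHABET= ACGU", ""]
    bg = np.asarray(background, dtype=float)
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)))
    lines.append("")
    for ppm in ppms:
        m = ppm.matrix
        if smoothing > 0:
            m = (m + smoothing) / (1 + 4 * smoothing)
        lines.append(f"MOTIF {ppm.label()}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {ppm.width} "
            f"nsites= {ppm.support} E= 0"
        )
        for row in m:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_meme(path: str | Path) -> list[PPM]:
    """Read back a MEME minimal motif file written by :func:`write_meme`."""
    text = Path(path).read_text()
    ppms = []
    blocks = re.split(r"(?m)^MOTIF\s+", text)[1:]
    for block in blocks:
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        name = lines[0].split()[0]
        header = next(ln for ln in lines if ln.startswith("letter-probability"))
        w = int(re.search(r"w=\s*(\d+)", header).group(1))
        ns = re.search(r"nsites=\s*(\d+)", header)
        support = int(ns.group(1)) if ns else 1
        start = lines.index(header) + 1
        rows = [[float(v) for v in ln.split()] for ln in lines[start : start + w]]
        mat = np.array(rows)
        mat = mat / mat.sum(axis=1, keepdims=True)  # renormalize rounding residue
        m = re.fullmatch(r"(?:(sa|sd)_)?filter(\d+)", name)
        ppms.append(
            PPM(
                matrix=mat,
                filter_index=int(m.group(2)) if m else -1,
                branch=m.group(1) or "" if m else "",
                support=support,
                name="" if m else name,
            )
        )
    return ppms


# ---------------------------------------------------------------------------
# occurrence scanning and positional analysis


def scan_occurrences(
    model: TrainedModel,
    pairs: Sequence[SamplePair],
    branch: str,
    filter_index: int,
    threshold_fraction: float = 0.5,
) -> list[MotifOccurrence]:
    """All window positions where a filter fires strongly.

    A position counts as an occurrence when its activation is at least
    ``threshold_fraction`` times the filter's maximum activation over the
    scanned set.  Occurrences carry the sample's label so positives and
    negatives can be profiled separately.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0,1]")
    if not pairs:
        return []
    k = filter_index
    if not 0 <= k < model.config.conv1_kernels:
        raise IndexError(f"filter index {k} out of range")
    acts = first_layer_activations(model, pairs, branch)[:, :, k]  # (n, P)
    peak = float(acts.max())
    if peak <= 0:
        return []
    width = model.config.conv1_size
    cutoff = threshold_fraction * peak
    out = []
    for i, p in enumerate(pairs):
        for s in np.nonzero(acts[i] >= cutoff)[0]:
            out.append(
                MotifOccurrence(
                    filter_index=k,
                    branch=branch.lower(),
                    seq_id=p.id,
                    label=p.label,
                    start=int(s),
                    side=_side_of(branch, int(s), width),
                    score=float(acts[i, s]),
                )
            )
    return out


def occurrence_density(
    occurrences: Sequence[MotifOccurrence],
    n_pos: int,
    n_neg: int,
    n_positions: int,
    smooth_window: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-start-position occurrence density for positives and negatives.

    density[p] = occurrences starting at p / number of scanned sequences
    of that class, so each profile sums to the mean occurrence count per
    sequence.  ``smooth_window`` applies a centered moving average (for
    plotting only).
    """
    if n_pos <= 0 and n_neg <= 0:
        raise ValueError("no scanned sequences")
    pos = np.zeros(n_positions)
    neg = np.zeros(n_positions)
    for o in occurrences:
        (pos if o.label == 1 else neg)[o.start] += 1
    if n_pos > 0:
        pos /= n_pos
    if n_neg > 0:
        neg /= n_neg
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        pos = np.convolve(pos, kern, mode="same")
        neg = np.convolve(neg, kern, mode="same")
    return pos, neg


def intron_exon_ratio(occurrences: Sequence[MotifOccurrence]) -> tuple[float, float]:
    """(fraction in intron, fraction in exon) over positive occurrences."""
    pos = [o for o in occurrences if o.label == 1]
    if not pos:
        raise NoOccurrences("no positive-sample occurrences")
    n_intron = sum(1 for o in pos if o.side == "intron")
    return n_intron / len(pos), 1.0 - n_intron / len(pos)


def occurrences_to_frame(occurrences: Sequence[MotifOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(o) for o in occurrences],
        columns=["filter_index", "branch", "seq_id", "label", "start", "side", "score"],
    )


# ---------------------------------------------------------------------------
# PPM set comparison (internal approximation of cross-species motif matching)


def ppm_match_score(a: PPM | np.ndarray, b: PPM | np.ndarray, min_overlap: int = 5):
    """Best ungapped alignment score between two PPMs.

    Slides b across a over every offset keeping >= min_overlap columns;
    the score of an offset is the mean per-column Pearson correlation of
    the probability 4-vectors over the overlap.  Returns (score, offset)
    where offset is the start of b relative to a.
    """
    ma = a.matrix if isinstance(a, PPM) else np.asarray(a, dtype=float)
    mb = b.matrix if isinstance(b, PPM) else np.asarray(b, dtype=float)
    wa, wb = len(ma), len(mb)
    if min(wa, wb) < min_overlap:
        return float("-inf"), 0
    best = (float("-inf"), 0)
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(wa, off + wb)
        if hi_a - lo_a < min_overlap:
            continue
        sa = ma[lo_a:hi_a]
        sb = mb[lo_a - off : hi_a - off]
        cors = []
        for ra, rb in zip(sa, sb):
            va, vb = ra - ra.mean(), rb - rb.mean()
            denom = np.sqrt((va**2).sum() * (vb**2).sum())
            cors.append(0.0 if denom == 0 else float(va @ vb / denom))
        score = float(np.mean(cors))
        if score > best[0]:
            best = (score, off)
    return best


def compare_ppm_sets(
    set_a: Sequence[PPM],
    set_b: Sequence[PPM],
    min_overlap: int = 5,
    score_threshold: float = 0.8,
) -> pd.DataFrame:
    """All pairs (a, b) whose best ungapped match score clears the threshold.

    Columns: a_index, b_index, offset, score.  The relation is symmetric:
    comparing (b, a) yields the mirrored matches.
    """
    rows = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            score, off = ppm_match_score(a, b, min_overlap=min_overlap)
            if score >= score_threshold:
                rows.append({"a_index": i, "b_index": j, "offset": off, "score": score})
    return pd.DataFrame(rows, columns=["a_index", "b_index", "offset", "score"])
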