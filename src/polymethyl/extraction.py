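"""Cytosine context classification, per-read methylation calls and
bisulfite conversion-rate estimation.

Context is always classified from the reference, never from the read:
bisulfite conversion corrupts read-side context (a converted downstream C
turns CHH into what looks like CHG, etc.).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .records import (
    CONTEXT_BY_SYMBOL,
    BisulfiteRead,
    CytosineSite,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# byte codes
_A, _C, _G, _T = 65, 67, 71, 84
CONTEXT_CODES = {"CpG": 0, "CHG": 1, "CHH": 2}
CONTEXT_NAMES = ("CpG", "CHG", "CHH")
# XM symbols indexed by (context code, methylated)
_SYMBOLS = np.array([[ord("z"), ord("Z")],
                     [ord("x"), ord("X")],
                     [ord("h"), ord("H")]], dtype=np.uint8)


def classify_context(seq: str, pos: int, strand: str) -> str:
    """Classify the cytosine at ``pos`` on ``strand`` as CpG/CHG/CHH/unknown.

    On the plus strand the two plus-strand bases downstream define the
    context; on the minus strand the two downstream bases are read 5'->3' on
    the minus strand (upstream on the plus strand, complemented). Fewer than
    two downstream bases, or any non-ACGT base in the window, gives
    ``unknown``.
    """
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at +{pos} is {seq[pos]!r}, not C")
        window = seq[pos + 1:pos + 3]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"base at -{pos} is {seq[pos]!r}, not C on minus strand")
        window = "".join(COMPLEMENT.get(b, "N") for b in seq[max(0, pos - 2):pos][::-1])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(window) < 2 or any(b not in "ACGT" for b in window):
        return "unknown"
    if window[0] == "G":
        return "CpG"
    if window[1] == "G":
        return "CHG"
    return "CHH"


@dataclass
class ContextMap:
    """Vectorized per-contig context classification of every cytosine.

    ``plus_code``/``minus_code`` hold CONTEXT_CODES at classifiable cytosine
    positions on the respective strand and -1 elsewhere (non-cytosine,
    truncated context, or N in the window).
    """

    plus_code: np.ndarray  # int8, length L
    minus_code: np.ndarray

    @property
    def plus_mask(self) -> np.ndarray:
        return self.plus_code >= 0

    @property
    def minus_mask(self) -> np.ndarray:
        return self.minus_code >= 0


def build_context_map(seq: np.ndarray) -> ContextMap:
    """Classify every cytosine on both strands of a byte-encoded sequence."""
    L = seq.size
    plus = np.full(L, -1, dtype=np.int8)
    minus = np.full(L, -1, dtype=np.int8)
    valid = np.isin(seq, (_A, _C, _G, _T))

    is_c = seq == _C
    is_g = seq == _G
    if L >= 3:
        n1, n2 = seq[1:-1], seq[2:]
        ok = valid[1:-1] & valid[2:]
        code = np.where(n1 == _G, 0, np.where(n2 == _G, 1, 2)).astype(np.int8)
        sel = is_c[:-2] & ok
        plus[:-2][sel] = code[sel]
        # minus strand: downstream = complemented upstream plus-strand bases.
        # complement(x) == G  <=>  x == C
        p1, p2 = seq[1:-1], seq[:-2]
        okm = valid[1:-1] & valid[:-2]
        code_m = np.where(p1 == _C, 0, np.where(p2 == _C, 1, 2)).astype(np.int8)
        selm = is_g[2:] & okm
        minus[2:][selm] = code_m[selm]
    return ContextMap(plus_code=plus, minus_code=minus)


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def bytes_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class SiteCall:
    """One read x cytosine observation."""

    site: CytosineSite
    read_id: str
    methylated: bool


@dataclass
class ExtractionResult:
    calls: list[SiteCall] = field(default_factory=list)
    dropped_context_mismatch: int = 0
    dropped_unknown_context: int = 0


def extract_site_calls(
    reads: Iterable[BisulfiteRead],
    reference: dict[str, str],
    *,
    mapq_min: Optional[int] = None,
) -> ExtractionResult:
    """Turn methylation strings into per-site methylated/unmethylated calls.

    Upper-case symbols are methylated, lower-case unmethylated; ``.`` and
    U/u (unknown context) positions are ignored. Each symbol's context is
    checked against the reference; mismatches are dropped and counted. When
    ``mapq_min`` is given (observations feeding sub-genome assignment), reads
    at or below it are excluded entirely.
    """
    result = ExtractionResult()
    for read in reads:
        if mapq_min is not None and read.mapq <= mapq_min:
            continue
        seq = reference[read.contig]
        strand = "+" if read.xg == "CT" else "-"
        for offset, sym in enumerate(read.xm):
            if sym == ".":
                continue
            ctx = CONTEXT_BY_SYMBOL.get(sym)
            if ctx is None:
                result.dropped_context_mismatch += 1
                continue
            if ctx == "unknown":
                result.dropped_unknown_context += 1
                continue
            pos = read.pos + offset
            ref_ctx = classify_context(seq, pos, strand)
            if ref_ctx != ctx:
                result.dropped_context_mismatch += 1
                continue
            site = CytosineSite(read.contig, pos, strand, ctx)
            result.calls.append(SiteCall(site, read.read_id, sym.isupper()))
    return result


def estimate_conversion_rate(
    control_reads: Iterable[BisulfiteRead],
) -> Optional[float]:
    """Bisulfite conversion percentage from reads on an unmethylated control.

    Every cytosine observation on the read's converted strand counts; a
    converted observation reads T (lower-case methylation symbol), an
    unconverted one reads C (upper-case symbol). Returns None when there are
    no observations.
    """
    converted = 0
    total = 0
    for read in control_reads:
        for sym in read.xm:
            if sym in ".Uu":
                continue
            total += 1
            if sym.islower():
                converted += 1
    if total == 0:
        return None
    return 100.0 * converted / total


def conversion_rate_from_xm_matrix(xm: np.ndarray) -> Optional[float]:
    """Vectorized :func:`estimate_conversion_rate` over an XM byte matrix."""
    flat = xm.ravel()
    sym = flat[flat != ord(".")]
    sym = sym[(sym != ord("U")) & (sym != ord("u"))]
    if sym.size == 0:
        return None
    return 100.0 * float(np.count_nonzero(sym >= ord("a"))) / sym.size
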