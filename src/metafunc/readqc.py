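"""Read quality control: windowed end-trimming, adaptor binning, length filter.

The QC stage mirrors a standard Illumina preprocessing recipe for short
(~76 nt) single-end reads:

1. Reads containing adaptor sequence are set aside whole ("binned") rather
   than trimmed, so the adaptor bin is a per-read count.
2. Surviving reads are end-trimmed by stepping a fixed-width window (default
   5 nt) in from each end and removing every window whose mean Phred quality
   falls below the threshold (default 20); trimming stops at the first
   window whose mean reaches the threshold. The 5' end is processed first,
   then the 3' end of the 5'-trimmed read. If fewer than a full window of
   bases remain, the remainder is evaluated as a short terminal window under
   the same mean-quality rule.
3. Reads shorter than ``min_len`` (default 50 nt) after trimming are
   discarded.

Every input read ends in exactly one of three fates — kept, discarded as
too short, or binned as adaptor — so the fate counts partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence


class Fate(str, Enum):
    KEPT = "kept"
    DISCARDED_SHORT = "discarded_short"
    BINNED_ADAPTOR = "binned_adaptor"


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with one Phred score per base."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise MalformedReadError(
                f"read {self.read_id!r}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


class MalformedReadError(ValueError):
    """Raised when a read's bases and quality scores disagree in length."""


@dataclass(frozen=True)
class QCParams:
    window: int = 5
    min_mean_q: float = 20.0
    min_len: int = 50
    adaptor_min_match: int = 16

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_len < self.window:
            raise ValueError("min_len must be >= window")


@dataclass(frozen=True)
class QCOutcome:
    read_id: str
    fate: Fate
    trimmed_5p: int = 0
    trimmed_3p: int = 0


def _leading_trim(quals: Sequence[float], window: int, min_mean_q: float) -> int:
    """Number of bases to remove from the front under the window rule.

    Consecutive non-overlapping windows are evaluated from the end inward;
    a window with mean quality below the threshold is removed entirely and
    the scan advances, a window at or above it stops the scan. A terminal
    stub shorter than ``window`` is judged by the same mean rule.
    """
    pos = 0
    n = len(quals)
    while pos < n:
        chunk = quals[pos : pos + window]
        if sum(chunk) / len(chunk) >= min_mean_q:
            break
        pos += len(chunk)
    return pos


def trim_quality(read: ReadRecord, params: QCParams = QCParams()) -> ReadRecord:
    """Trim low-quality windows from both ends of a read.

    The 5' pass runs first; the 3' pass then runs on the 5'-trimmed read.
    May return a zero-length read when every window fails.
    """
    lead = _leading_trim(read.quals, params.window, params.min_mean_q)
    rest = read.quals[lead:]
    tail = _leading_trim(rest[::-1], params.window, params.min_mean_q)
    stop = len(read) - tail
    return replace(read, bases=read.bases[lead:stop], quals=read.quals[lead:stop])


class AdaptorIndex:
    """Seed-indexed adaptor matcher: ≥ ``min_match`` nt at ≤1 mismatch.

    A deterministic substring scan stands in for a local aligner: a read is
    flagged when any window of ``min_match`` bases matches a same-length
    window of any adaptor with at most one mismatch. By pigeonhole, such a
    window contains an exact seed of ``min_match // 2`` bases from one of
    its halves, so exact seed lookup prefilters the quadratic verification.
    """

    def __init__(self, adaptors: Sequence[str], min_match: int = 16):
        if not adaptors:
            raise ValueError("adaptor list must be non-empty")
        self.min_match = min_match
        self.seed_len = max(4, min_match // 2)
        self.windows: list[str] = []
        seeds: set[str] = set()
        for adaptor in adaptors:
            adaptor = adaptor.upper()
            if len(adaptor) < min_match:
                continue
            for i in range(len(adaptor) - min_match + 1):
                win = adaptor[i : i + min_match]
                self.windows.append(win)
                seeds.add(win[: self.seed_len])
                seeds.add(win[min_match - self.seed_len :])
        self.seeds = frozenset(seeds)

    def _verify(self, bases: str) -> bool:
        k = self.min_match
        for j in range(len(bases) - k + 1):
            sub = bases[j : j + k]
            for win in self.windows:
                mismatches = 0
                for a, b in zip(sub, win):
                    if a != b:
                        mismatches += 1
                        if mismatches > 1:
                            break
                if mismatches <= 1:
                    return True
        return False

    def matches(self, bases: str) -> bool:
        bases = bases.upper()
        if len(bases) < self.min_match:
            return False
        s = self.seed_len
        if not any(bases[j : j + s] in self.seeds for j in range(len(bases) - s + 1)):
            return False
        return self._verify(bases)


def bin_adaptor(
    read: ReadRecord, adaptors: Sequence[str] | AdaptorIndex, params: QCParams = QCParams()
) -> bool:
    """True iff the read contains ≥ ``adaptor_min_match`` nt of an adaptor at ≤1 mismatch."""
    index = adaptors if isinstance(adaptors, AdaptorIndex) else AdaptorIndex(adaptors, params.adaptor_min_match)
    return index.matches(read.bases)


def filter_length(read: ReadRecord, params: QCParams = QCParams()) -> bool:
    """True iff the (already trimmed) read is long enough to keep."""
    return len(read) >= params.min_len


@dataclass
class QCResult:
    kept: list[ReadRecord] = field(default_factory=list)
    outcomes: list[QCOutcome] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        tally = {fate.value: 0 for fate in Fate}
        for o in self.outcomes:
            tally[o.fate.value] += 1
        return tally


def run_qc(
    reads: Iterable[ReadRecord],
    adaptors: Sequence[str],
    params: QCParams = QCParams(),
) -> QCResult:
    """Run the full QC ladder: adaptor binning, quality trimming, length filter."""
    index = AdaptorIndex(adaptors, params.adaptor_min_match)
    result = QCResult()
    for read in reads:
        if index.matches(read.bases):
            result.outcomes.append(QCOutcome(read.read_id, Fate.BINNED_ADAPTOR))
            continue
        trimmed = trim_quality(read, params)
        t5 = _leading_trim(read.quals, params.window, params.min_mean_q)
        t3 = len(read) - t5 - len(trimmed)
        if filter_length(trimmed, params):
            result.kept.append(trimmed)
            result.outcomes.append(QCOutcome(read.read_id, Fate.KEPT, t5, t3))
        else:
            result.outcomes.append(QCOutcome(read.read_id, Fate.DISCARDED_SHORT, t5, t3))
    return result
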