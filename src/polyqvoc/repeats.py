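"""Hinge-anchored polyQ repeat calling for FOXP2/FOXP1 orthologs.

The two major polyglutamine repeats of these proteins (Q1 upstream, Q2
downstream) flank a short conserved "hinge" peptide — 'HPGKQAKE' in human
FOXP2, 'ALQVARQLLL' in human FOXP1.  The caller locates the hinge by a
substitution-only (Hamming) scan, then applies the field's repeat-calling
rules:

* a polyQ *run* is a maximal stretch of Q residues tolerating at most one
  embedded histidine (H counts toward the run length but may not start or
  end it);
* Q1 is read in a window upstream of the hinge.  If the upstream repeat
  region contains proline, Q1 is the run immediately N-terminal to the
  *first* proline and any fragmented runs between that proline and the hinge
  are ignored; otherwise Q1 is the longest run in the region;
* Q2 is the longest run starting within a window downstream of the hinge.
  Residues between the hinge and Q2 beyond a small canonical-context
  allowance are reported as a hinge extension (some predicted cetacean
  orthologs carry a 22-residue insertion here, likely a splice-prediction
  artifact) and excluded from Q2;
* per ortholog the sum S = Q1+Q2 and ratio R = Q1/Q2 are derived, the ratio
  at full precision;
* when a species has several isoforms, the one with the longest polyQ
  tracts (largest S) is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import NoHingeError
from .io import OrthologRecord

#: canonical hinge anchors per gene
ANCHORS = {"FOXP2": "HPGKQAKE", "FOXP1": "ALQVARQLLL"}

# quality-flag codes
NO_HINGE = "no_hinge"
NO_Q1 = "no_q1"
NO_Q2 = "no_q2"
HINGE_EXTENSION = "hinge_extension"
ISOFORM_TIE = "isoform_tie"


@dataclass(frozen=True)
class HingeConfig:
    """Parameters of hinge-anchored repeat calling.

    ``context_allowance`` is the number of residues between hinge end and Q2
    start treated as canonical spacing rather than an extension.
    """

    gene: str = "FOXP2"
    anchor: Optional[str] = None
    max_mismatch: int = 2
    upstream_window: int = 100
    downstream_window: int = 60
    min_run: int = 2
    context_allowance: int = 4

    def __post_init__(self):
        if self.anchor is None:
            object.__setattr__(self, "anchor", ANCHORS[self.gene])
        if len(self.anchor) < 6:
            raise ValueError("anchor must be at least 6 residues")
        if self.max_mismatch >= len(self.anchor) / 2:
            raise ValueError("max_mismatch must be < anchor length / 2")
        if self.upstream_window <= 0 or self.downstream_window <= 0:
            raise ValueError("windows must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be positive")


@dataclass(frozen=True)
class HingeMatch:
    """Best hinge placement: 0-based half-open interval plus mismatch count."""

    start: int
    end: int
    mismatches: int
    matched_text: str


@dataclass(frozen=True)
class QRun:
    """A histidine-tolerant polyQ run (0-based half-open interval)."""

    start: int
    end: int
    has_h: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatCall:
    """Q1/Q2 call for one sequence.

    Numeric fields are ``None`` on flagged (failed) calls; ``ok`` is True
    when both repeats were called.  ``ratio_r`` is stored at full precision.
    """

    hinge: Optional[HingeMatch]
    q1_len: Optional[int] = None
    q2_len: Optional[int] = None
    q1_interval: Optional[tuple[int, int]] = None
    q2_interval: Optional[tuple[int, int]] = None
    extension_len: int = 0
    q1_contains_histidine: bool = False
    q1_truncated_by_proline: bool = False
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return not self.flags.intersection({NO_HINGE, NO_Q1, NO_Q2})

    @property
    def sum_s(self) -> Optional[int]:
        if self.q1_len is None or self.q2_len is None:
            return None
        return self.q1_len + self.q2_len

    @property
    def ratio_r(self) -> Optional[float]:
        if self.q1_len is None or not self.q2_len:
            return None
        return self.q1_len / self.q2_len


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def find_hinge(seq: str, cfg: HingeConfig) -> HingeMatch:
    """Locate the hinge anchor by exhaustive substitution-only scan.

    Returns the window with the fewest mismatches (leftmost on ties).

    Raises
    ------
    NoHingeError
        If no window is within ``cfg.max_mismatch`` substitutions; the error
        carries the best distance found.
    """
    anchor = cfg.anchor
    k = len(anchor)
    best_start, best_d = -1, k + 1
    for start in range(len(seq) - k + 1):
        d = 0
        window = seq[start : start + k]
        for x, y in zip(window, anchor):
            if x != y:
                d += 1
                if d >= best_d:
                    break
        if d < best_d:
            best_start, best_d = start, d
            if d == 0:
                break
    if best_start < 0 or best_d > cfg.max_mismatch:
        raise NoHingeError(
            f"no hinge within {cfg.max_mismatch} mismatches of {anchor!r} "
            f"(best distance {best_d if best_start >= 0 else 'n/a'})",
            best_mismatches=best_d if best_start >= 0 else None,
        )
    return HingeMatch(
        start=best_start,
        end=best_start + k,
        mismatches=best_d,
        matched_text=seq[best_start : best_start + k],
    )


def _pure_runs(seq: str, lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal pure-Q runs intersected with [lo, hi)."""
    runs = []
    i = lo
    while i < hi:
        if seq[i] == "Q":
            j = i
            while j < hi and seq[j] == "Q":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def q_runs(seq: str, lo: int, hi: int) -> list[QRun]:
    """All candidate histidine-tolerant runs within [lo, hi).

    Candidates are the maximal pure-Q runs plus every merge of two adjacent
    pure runs separated by exactly one H (the H is interior and counts 1
    toward the length).  At most one H per run.
    """
    pure = _pure_runs(seq, lo, hi)
    runs = [QRun(s, e) for s, e in pure]
    for (s1, e1), (s2, e2) in zip(pure, pure[1:]):
        if s2 - e1 == 1 and seq[e1] == "H":
            runs.append(QRun(s1, e2, has_h=True))
    runs.sort(key=lambda r: (r.start, -r.length))
    return runs


def _longest(runs: Sequence[QRun]) -> QRun:
    # longest wins; leftmost on ties
    return max(runs, key=lambda r: (r.length, -r.start))


def call_repeats(seq: str, cfg: HingeConfig) -> RepeatCall:
    """Call Q1, Q2, sum, ratio and hinge extension on a normalized sequence.

    See the module docstring for the calling rules.  Missing repeats yield a
    flagged call (``no_q1`` / ``no_q2``) instead of an error; an unfindable
    hinge raises :class:`NoHingeError` (panel-level helpers catch it and
    emit a ``no_hinge`` flagged row).
    """
    hinge = find_hinge(seq, cfg)
    flags: set[str] = set()

    # --- Q2: longest run starting within the downstream window ------------
    down_hi = len(seq)
    candidates = [
        r
        for r in q_runs(seq, hinge.end, down_hi)
        if r.start - hinge.end <= cfg.downstream_window and r.length >= cfg.min_run
    ]
    q2_run = None
    extension_len = 0
    if not candidates:
        flags.add(NO_Q2)
    else:
        q2_run = _longest(candidates)
        gap = q2_run.start - hinge.end
        if gap > cfg.context_allowance:
            extension_len = gap
            flags.add(HINGE_EXTENSION)

    # --- Q1: upstream repeat region with first-proline truncation ---------
    up_lo = max(0, hinge.start - cfg.upstream_window)
    up_runs = q_runs(seq, up_lo, hinge.start)
    qualifying = [r for r in up_runs if r.length >= cfg.min_run]
    q1_run = None
    truncated = False
    if not qualifying:
        flags.add(NO_Q1)
    else:
        region_start = min(r.start for r in qualifying)
        first_p = seq.find("P", region_start, hinge.start)
        if first_p >= 0:
            # run immediately N-terminal to the first proline; fragmented
            # runs between that proline and the hinge are ignored
            before = [r for r in up_runs if r.end <= first_p]
            if before:
                rightmost_end = max(r.end for r in before)
                q1_run = _longest([r for r in before if r.end == rightmost_end])
                truncated = True
            else:
                flags.add(NO_Q1)
        else:
            q1_run = _longest([r for r in up_runs if r.start >= region_start])
        if q1_run is not None and q1_run.length < cfg.min_run:
            q1_run = None
            truncated = False
            flags.add(NO_Q1)

    return RepeatCall(
        hinge=hinge,
        q1_len=q1_run.length if q1_run else None,
        q2_len=q2_run.length if q2_run else None,
        q1_interval=(q1_run.start, q1_run.end) if q1_run else None,
        q2_interval=(q2_run.start, q2_run.end) if q2_run else None,
        extension_len=extension_len,
        q1_contains_histidine=bool(q1_run and q1_run.has_h),
        q1_truncated_by_proline=truncated,
        flags=frozenset(flags),
    )


def call_record(record: OrthologRecord, cfg: HingeConfig) -> RepeatCall:
    """Call one ortholog record; an unfindable hinge becomes a flagged call."""
    try:
        return call_repeats(record.sequence, cfg)
    except NoHingeError:
        return RepeatCall(hinge=None, flags=frozenset({NO_HINGE}))


def select_longest_isoform(
    records: Sequence[OrthologRecord], cfg: HingeConfig
) -> tuple[OrthologRecord, RepeatCall]:
    """Pick the isoform with the longest polyQ tracts (largest Q1+Q2 sum).

    Flagged records rank below all successfully called records.  Ties on the
    sum keep the first record in input order and add an ``isoform_tie`` flag.
    If every record is flagged, the first record's flagged call propagates.
    """
    if not records:
        raise ValueError("select_longest_isoform requires at least one record")
    calls = [call_record(rec, cfg) for rec in records]
    called = [(rec, c) for rec, c in zip(records, calls) if c.ok]
    if not called:
        return records[0], calls[0]
    best_sum = max(c.sum_s for _, c in called)
    winners = [(rec, c) for rec, c in called if c.sum_s == best_sum]
    rec, call = winners[0]
    if len(winners) > 1:
        call = replace(call, flags=call.flags | {ISOFORM_TIE})
    return rec, call
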