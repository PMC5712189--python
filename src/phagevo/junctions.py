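"""Base-precision deletion junctions and flanking direct repeats.

A deletion between two direct repeats leaves one repeat copy, so the exact
junction is ambiguous over repeat-length + 1 equivalent placements.  The
canonical placement reported here is the leftmost one; the repeat sequence and
the size of the equivalence class are reported alongside so any other
convention can be matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_utils import GenomeRecord, Interval
from .variants import GapBlock


class JunctionError(ValueError):
    pass


@dataclass
class JunctionCall:
    parent_id: str
    derived_id: str
    parent_interval: Interval          # deleted bases on the parent, 1-based
    derived_flanks: tuple[int, int]    # (last base before, first base after) on derived
    repeat: str                        # flanking direct repeat ('' when none)
    repeat_length: int
    ambiguity: int                     # number of equivalent placements = repeat_length + 1
    terminal: bool = False             # deletion abuts a genome end; repeat one-sided

    @property
    def length(self) -> int:
        return self.parent_interval.length


def _shift_counts(seq: str, start0: int, end0: int, max_len: int) -> tuple[int, int]:
    """How far the deletion [start0, end0) of ``seq`` can slide left and right
    while producing the same derived sequence."""
    left = 0
    while (left < max_len and start0 - left - 1 >= 0
           and seq[start0 - left - 1] == seq[end0 - left - 1]):
        left += 1
    right = 0
    while (right < max_len and end0 + right < len(seq)
           and seq[start0 + right] == seq[end0 + right]):
        right += 1
    return left, right


def find_flanking_repeat(parent: GenomeRecord, deletion: Interval,
                         max_len: int = 50) -> tuple[str, int, int]:
    """Longest direct repeat making the deletion junction ambiguous.

    Returns ``(repeat_sequence, repeat_length, ambiguity_window)`` where the
    ambiguity window is repeat_length + 1 (the number of equivalent deletion
    placements).  The repeat is the maximal exact overlap between the sequence
    entering and leaving the deleted segment; length 0 (no repeat) is allowed.
    A deletion at a genome terminus is searched on the available side only.
    """
    if deletion.end > len(parent.seq):
        raise JunctionError(f"deletion {deletion} outside {parent.id}")
    s0, e0 = deletion.start - 1, deletion.end  # 0-based half-open
    left, right = _shift_counts(parent.seq, s0, e0, max_len)
    r = min(left + right, max_len)
    # repeat as seen at the leftmost-equivalent placement
    start_leftmost = s0 - left
    repeat = parent.seq[start_leftmost: start_leftmost + r]
    return repeat, r, r + 1


def locate_junction(parent: GenomeRecord, derived: GenomeRecord,
                    block: GapBlock, flank: int = 20,
                    max_repeat: int = 50) -> JunctionCall:
    """Refine a gap block (present in ``parent``, absent in ``derived``) to a
    base-precision deletion junction in the leftmost-equivalent placement.

    The parent sequence with the reported interval excised must equal the
    derived sequence over ``flank`` exact bases on each side; otherwise the gap
    block was misassigned and an error is raised.
    """
    if not block.presence.get(parent.id, False):
        raise JunctionError(f"{parent.id} has no sequence over block {block.block_id}")
    if block.presence.get(derived.id, True):
        raise JunctionError(f"{derived.id} is not absent over block {block.block_id}")
    ps, pe = block.coords[parent.id]         # 1-based inclusive on parent
    dflank = block.flanks[derived.id]        # 1-based coord of last base before
    s0, e0 = ps - 1, pe                      # 0-based half-open on parent

    # shift to the leftmost equivalent placement
    left, _ = _shift_counts(parent.seq, s0, e0, max_len=max(max_repeat, 1))
    s0 -= left
    e0 -= left
    d_before = dflank - left                 # derived coord of last base before junction

    # verify the reconstruction identity over the flanks
    terminal = s0 == 0 or e0 == len(parent.seq)
    p_left = parent.seq[max(0, s0 - flank): s0]
    p_right = parent.seq[e0: e0 + flank]
    d_left = derived.seq[max(0, d_before - flank): d_before]
    d_right = derived.seq[d_before: d_before + flank]
    if p_left != d_left or p_right != d_right:
        raise JunctionError(
            f"flanks do not match between {parent.id} and {derived.id} around "
            f"block {block.block_id}: the gap block may be misassigned"
        )
    interval = Interval(s0 + 1, e0)
    repeat, rlen, window = find_flanking_repeat(parent, interval, max_len=max_repeat)
    return JunctionCall(
        parent_id=parent.id, derived_id=derived.id,
        parent_interval=interval,
        derived_flanks=(d_before, d_before + 1),
        repeat=repeat, repeat_length=rlen, ambiguity=window,
        terminal=terminal,
    )


def stoperator_mediated_check(deletion: Interval, hits: Sequence,
                              slack: int = 5) -> tuple[bool, Optional[tuple]]:
    """Did the deletion arise by recombination between two same-orientation
    motif (stoperator) sites?

    True when both deletion boundaries fall within (or within ``slack`` bp of)
    motif hits of the same orientation; the two site ids are returned.  ``hits``
    are MotifHit objects on the parent genome.
    """
    def near(boundary: int, hit) -> bool:
        return hit.interval.start - slack <= boundary <= hit.interval.end + slack

    left_hits = [h for h in hits if near(deletion.start, h)]
    right_hits = [h for h in hits if near(deletion.end + 1, h) or near(deletion.end, h)]
    for lh in left_hits:
        for rh in right_hits:
            if lh is rh:
                continue
            if lh.strand == rh.strand:
                return True, (lh.site_id, rh.site_id)
    return False, None


def write_junction_table(calls: Sequence[JunctionCall], path,
                         mediated: Optional[dict[int, tuple]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("# parent\tderived\tparent_start\tparent_end\tlength\t"
                 "derived_before\tderived_after\trepeat\trepeat_len\t"
                 "ambiguity\tstoperator_mediated\n")
        for i, c in enumerate(calls):
            med = mediated.get(i) if mediated else None
            fh.write(f"{c.parent_id}\t{c.derived_id}\t{c.parent_interval.start}\t"
                     f"{c.parent_interval.end}\t{c.length}\t{c.derived_flanks[0]}\t"
                     f"{c.derived_flanks[1]}\t{c.repeat or '.'}\t{c.repeat_length}\t"
                     f"{c.ambiguity}\t{'yes' if med else 'no'}\n")
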