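"""Site-relative window enumeration.

Offsets are integers with no 0: ..., -2, -1, +1, +2, ...  The cleavage
point sits between -1 and +1.  Internally a window over a +/- ``m`` region
is a pair of *slots* in ``[0, 2m)``; slot ``i`` corresponds to transcript
position ``site - m + i`` where ``site`` is the transcript coordinate of
the +1 nucleotide (the detected 5' end).
"""

from __future__ import annotations

Window = tuple[int, int]  # (offset_start, offset_end), inclusive, no 0


def slot_to_offset(slot: int, max_offset: int) -> int:
    if not 0 <= slot < 2 * max_offset:
        raise ValueError(f"slot {slot} outside [0, {2 * max_offset})")
    return slot - max_offset if slot < max_offset else slot - max_offset + 1


def offset_to_slot(offset: int, max_offset: int) -> int:
    if offset == 0:
        raise ValueError("offset 0 does not exist; the cut lies between -1 and +1")
    if not -max_offset <= offset <= max_offset:
        raise ValueError(f"offset {offset} outside +/-{max_offset}")
    return offset + max_offset if offset < 0 else offset + max_offset - 1


def window_length(window: Window) -> int:
    start, end = window
    if start == 0 or end == 0 or end < start:
        raise ValueError(f"malformed window {window}")
    n = end - start + 1
    if start < 0 < end:  # offset 0 is skipped
        n -= 1
    return n


def window_transcript_span(window: Window, site: int) -> tuple[int, int]:
    """Half-open transcript-coordinate span covered by ``window`` at ``site``.

    ``site`` is the transcript position of the +1 nucleotide.
    """
    start, end = window
    a = site + start if start < 0 else site + start - 1
    b = site + end if end < 0 else site + end - 1
    return a, b + 1


def enumerate_site_windows(
    max_offset: int, min_len: int, max_len: int, step: int = 1
) -> list[Window]:
    """All windows of lengths ``min_len..max_len`` (stepping by ``step``)
    placed at every ``step`` within the +/- ``max_offset`` region.

    The same ``step`` increments both the window length and its placement,
    matching sliding-window enumeration shifted one position (or one block)
    at a time.
    """
    if min(max_offset, min_len, max_len, step) < 1:
        raise ValueError("all window parameters must be positive")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    span = 2 * max_offset
    if max_len > span:
        raise ValueError(f"max_len {max_len} exceeds region size {span}")
    windows: list[Window] = []
    for length in range(min_len, max_len + 1, step):
        for s in range(0, span - length + 1, step):
            windows.append(
                (slot_to_offset(s, max_offset), slot_to_offset(s + length - 1, max_offset))
            )
    return windows
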