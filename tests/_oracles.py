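"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives the expected result by direct enumeration, sharing no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_ptm_hotspot_centers(positions, k, flank=7):
    """O(n^2) window counter: centers with >= k other sites within +/-flank."""
    pos = sorted(set(positions))
    out = []
    for c in pos:
        n = sum(1 for s in pos if s != c and abs(s - c) <= flank)
        if n >= k:
            out.append(c)
    return out


def brute_crosstalk_hotspot_centers(positions, k, flank=7, include_center=True):
    pos = sorted(set(positions))
    out = []
    for c in pos:
        n = sum(1 for s in pos if abs(s - c) <= flank)
        if not include_center:
            n -= 1
        if n >= k:
            out.append(c)
    return out


def mask_stitch(windows, L):
    """Boolean-mask union oracle: merged intervals and exact coverage."""
    mask = np.zeros(L + 2, dtype=bool)  # 1-based, sentinel at both ends
    for start, end in windows:
        mask[start : end + 1] = True
    intervals = []
    i = 1
    while i <= L:
        if mask[i]:
            j = i
            while j + 1 <= L and mask[j + 1]:
                j += 1
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return intervals, mask[1 : L + 1].sum() / L


def regions_to_mask(regions, L):
    """Boolean occupancy of a region list, 1-based."""
    mask = np.zeros(L + 2, dtype=bool)
    for r in regions:
        mask[r.start : r.end + 1] = True
    return mask


def merge_adjacent(intervals):
    """Collapse end+1 == start runs, for comparing against a mask union
    (which cannot distinguish adjacent intervals from merged ones)."""
    out = []
    for start, end in sorted(intervals):
        if out and start == out[-1][1] + 1:
            out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def brute_mav_pairs(variant_positions, site_positions, flank=7):
    """Cross-join filter |v - s| <= flank, one pair per qualifying (v, s)."""
    return sorted(
        (v, s)
        for v in variant_positions
        for s in site_positions
        if abs(v - s) <= flank
    )


def brute_crosstalk_sites(raw_rows):
    """Group-by oracle over (accession, position) -> set of canonical types.

    ``raw_rows`` is an iterable of (accession, position, canonical_type,
    source) tuples, possibly with multi-source duplicates.  Returns the
    sorted crosstalk keys and the combination census.
    """
    groups: dict[tuple, set] = {}
    for acc, pos, ptype, _src in raw_rows:
        groups.setdefault((acc, pos), set()).add(ptype)
    crosstalk = sorted(key for key, types in groups.items() if len(types) >= 2)
    census: dict[str, int] = {}
    for key in crosstalk:
        combo = "+".join(sorted(groups[key]))
        census[combo] = census.get(combo, 0) + 1
    return crosstalk, census
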