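"""Brute-force oracles shared by the test modules."""

import numpy as np


def flood_fill_partition(mask, connectivity=26):
    """Partition a 3D boolean mask into connected groups by explicit
    stack-based flood fill (independent of any labelling library)."""
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)
               and (abs(dz) + abs(dy) + abs(dx) == 1 or connectivity == 26)]
    seen = np.zeros(mask.shape, bool)
    groups = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, group = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            group.append(v)
            for off in offsets:
                n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                        and mask[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
        groups.append(frozenset(group))
    return set(groups)
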