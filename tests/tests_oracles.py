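"""Brute-force reference implementations used only by the test suite."""

import numpy as np


def flood_fill_gap_areas(mask: np.ndarray) -> list[int]:
    """Pixel areas of 8-connected holes (inverted foreground) that do not
    touch the raster border, by breadth-first flood fill."""
    gaps = ~mask
    seen = np.zeros_like(gaps, dtype=bool)
    h, w = gaps.shape
    areas = []
    for i in range(h):
        for j in range(w):
            if gaps[i, j] and not seen[i, j]:
                stack, area, touches = [(i, j)], 0, False
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    area += 1
                    if a in (0, h - 1) or b in (0, w - 1):
                        touches = True
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if (
                                0 <= na < h
                                and 0 <= nb < w
                                and gaps[na, nb]
                                and not seen[na, nb]
                            ):
                                seen[na, nb] = True
                                stack.append((na, nb))
                if not touches:
                    areas.append(area)
    return areas
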