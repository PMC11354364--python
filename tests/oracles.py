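"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the entropy oracle
loops over every pixel and every disk offset explicitly and builds the
histogram with numpy.unique; the disk oracle enumerates the integer lattice
exhaustively.
"""

import numpy as np


def brute_force_disk_count(radius: int) -> int:
    """Count lattice points (dy, dx) with dy^2 + dx^2 <= radius^2."""
    n = 0
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                n += 1
    return n


def brute_force_entropy(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) over the closed disk, reflect-padded."""
    pad = np.pad(pixels, radius, mode="reflect")
    h, w = pixels.shape
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.zeros((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            vals = [pad[y + radius + dy, x + radius + dx] for dy, dx in offsets]
            _, counts = np.unique(np.array(vals), return_counts=True)
            p = counts / counts.sum()
            out[y, x] = float(-(p * np.log2(p)).sum())
    return out
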