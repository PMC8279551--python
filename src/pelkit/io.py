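"""Multi-frame XYZ reading and writing.

Standard XYZ: atom count line, comment line, then one ``element x y z`` line
per atom; frames concatenated.  Frame order matches database record order
when used alongside the stationary-point files.
"""

from __future__ import annotations

import numpy as np


def write_xyz(path, frames, elements, comments=None) -> None:
    """Write frames (iterable of (N,3) or flat arrays) to a multi-frame XYZ."""
    frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
    n = len(elements)
    with open(str(path), "w") as fh:
        for k, f in enumerate(frames):
            if f.shape[0] != n:
                raise ValueError(f"frame {k} has {f.shape[0]} atoms, expected {n}")
            comment = "" if comments is None else str(comments[k])
            fh.write(f"{n}\n{comment}\n")
            for el, row in zip(elements, f):
                fh.write(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}\n")


def read_xyz(path) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Read a multi-frame XYZ; returns (frames, elements, comments)."""
    frames: list[np.ndarray] = []
    comments: list[str] = []
    elements: list[str] = []
    with open(str(path)) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        comments.append(lines[pos + 1] if pos + 1 < len(lines) else "")
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"truncated XYZ frame at line {pos + 1}")
        frame = np.empty((n, 3))
        els = []
        for i, ln in enumerate(block):
            parts = ln.split()
            els.append(parts[0])
            frame[i] = [float(v) for v in parts[1:4]]
        if not elements:
            elements = els
        frames.append(frame)
        pos += 2 + n
    return frames, elements, comments
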