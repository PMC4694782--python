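"""Read/write PWMs in MEME minimal motif format."""

from __future__ import annotations

import numpy as np

from .motif import Pwm

__all__ = ["write_meme", "read_meme"]

_HEADER = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}
"""


def write_meme(pwms: dict[str, Pwm], path) -> None:
    first = next(iter(pwms.values()))
    with open(path, "w") as fh:
        fh.write(_HEADER.format(bg=first.background))
        for name, pwm in pwms.items():
            fh.write(f"\nMOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme(path) -> dict[str, Pwm]:
    pwms: dict[str, Pwm] = {}
    background = np.full(4, 0.25)
    name = None
    rows: list[list[float]] = []
    expect = 0

    def flush():
        nonlocal name, rows
        if name is not None and rows:
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pwms[name] = Pwm(probs=np.clip(probs, 1e-9, None)
                             / np.clip(probs, 1e-9, None).sum(axis=1, keepdims=True),
                             background=background.copy())
        name, rows = None, []

    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "Background" and "frequencies" in line:
                freq_line = next(lines).split()
                background = np.array([float(freq_line[i]) for i in (1, 3, 5, 7)])
            elif tokens[0] == "MOTIF":
                flush()
                name = tokens[1]
            elif tokens[0] == "letter-probability":
                expect = int(tokens[tokens.index("w=") + 1])
            elif name is not None and len(tokens) == 4 and len(rows) < expect:
                try:
                    rows.append([float(t) for t in tokens])
                except ValueError:
                    pass
    flush()
    return pwms
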