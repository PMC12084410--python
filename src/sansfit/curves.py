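"""Reduced 1-D scattering curves and their ASCII file format.

A reduced small-angle scattering curve is three or four columns of numbers:
momentum transfer Q in 1/Angstrom, intensity I(Q), its uncertainty sigma_I,
and optionally a per-point resolution width sigma_Q.  Header lines start
with ``#`` and may carry ``key: value`` metadata (the simulator records its
generation parameters this way).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScatteringCurve", "CurveFormatError", "read_curve", "write_curve"]


class CurveFormatError(ValueError):
    """Raised when a reduced-data file cannot be parsed; names the line."""


@dataclass
class ScatteringCurve:
    """One reduced 1-D scattering curve.

    Q must be strictly increasing and positive; all arrays share a length.
    """

    Q: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray
    sigma_Q: np.ndarray | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma_I = np.asarray(self.sigma_I, dtype=float)
        if self.sigma_Q is not None:
            self.sigma_Q = np.asarray(self.sigma_Q, dtype=float)
        n = self.Q.size
        for name in ("I", "sigma_I"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} has length {getattr(self, name).size}, "
                                 f"expected {n}")
        if self.sigma_Q is not None and self.sigma_Q.size != n:
            raise ValueError("sigma_Q length mismatch")
        if n == 0:
            raise ValueError("empty curve")
        if np.any(self.Q <= 0):
            raise ValueError("Q must be positive")
        if np.any(np.diff(self.Q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite")
        if np.any(self.sigma_I < 0):
            raise ValueError("sigma_I must be >= 0")
        if self.sigma_Q is not None and np.any(self.sigma_Q < 0):
            raise ValueError("sigma_Q must be >= 0")

    def __len__(self) -> int:
        return self.Q.size

    def window(self, qmin: float, qmax: float) -> "ScatteringCurve":
        """Sub-curve with qmin <= Q <= qmax."""
        m = (self.Q >= qmin) & (self.Q <= qmax)
        if not np.any(m):
            raise ValueError(f"no points in [{qmin}, {qmax}]")
        return ScatteringCurve(
            self.Q[m], self.I[m], self.sigma_I[m],
            None if self.sigma_Q is None else self.sigma_Q[m],
            label=self.label, metadata=dict(self.metadata))

    def subtract_background(self, background: float) -> "ScatteringCurve":
        return ScatteringCurve(
            self.Q, self.I - background, self.sigma_I, self.sigma_Q,
            label=self.label, metadata=dict(self.metadata))


def read_curve(path) -> ScatteringCurve:
    """Read a 3- or 4-column ASCII reduced-data file.

    ``#``-prefixed header lines of the form ``# key: value`` are collected
    into ``metadata`` (values parsed as float where possible).
    """
    metadata: dict = {}
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    val = val.strip()
                    try:
                        metadata[key.strip()] = float(val)
                    except ValueError:
                        metadata[key.strip()] = val
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise CurveFormatError(
                    f"{path}: line {lineno}: non-numeric data {line!r}")
            if len(vals) not in (3, 4):
                raise CurveFormatError(
                    f"{path}: line {lineno}: expected 3 or 4 columns, "
                    f"got {len(vals)}")
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise CurveFormatError(
                    f"{path}: line {lineno}: inconsistent column count")
            rows.append(vals)
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    arr = np.array(rows)
    sigma_Q = arr[:, 3] if arr.shape[1] == 4 else None
    label = str(metadata.get("label", ""))
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], sigma_Q,
                           label=label, metadata=metadata)


def write_curve(curve: ScatteringCurve, path, metadata: dict | None = None) -> None:
    """Write a curve with its metadata as ``# key: value`` header lines.

    Values are written with full float precision so a read round-trips
    bit-exactly.
    """
    meta = dict(curve.metadata)
    if metadata:
        meta.update(metadata)
    if curve.label and "label" not in meta:
        meta["label"] = curve.label
    with open(path, "w") as fh:
        fh.write("# columns: Q[1/A] I sigma_I" +
                 (" sigma_Q\n" if curve.sigma_Q is not None else "\n"))
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        cols = [curve.Q, curve.I, curve.sigma_I]
        if curve.sigma_Q is not None:
            cols.append(curve.sigma_Q)
        for row in zip(*cols):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
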