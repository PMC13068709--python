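"""Shared sweep-result container: drain current versus a sweep variable."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

X_KINDS = ("v_cg", "concentration", "fraction")


@dataclass(frozen=True)
class ResponseCurve:
    """Drain current versus a sweep variable (gate bias, occupancy or [T])."""

    x: np.ndarray
    current: np.ndarray
    x_kind: str
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "current", i)
        if self.x_kind not in X_KINDS:
            raise ValidationError(f"x_kind must be one of {X_KINDS}, got {self.x_kind!r}")
        if x.ndim != 1 or x.size == 0:
            raise ValidationError("x must be a non-empty 1-D array")
        if i.shape != x.shape:
            raise ValidationError("current must match x in length")
        if x.size > 1 and np.any(np.diff(x) < 0):
            raise ValidationError("x must be sorted ascending")

    def __len__(self) -> int:
        return int(self.x.size)

    _COLUMNS = {"v_cg": "v_cg_V", "concentration": "concentration_M",
                "fraction": "bound_fraction"}

    def to_csv(self, path_or_buf, extra_columns: dict | None = None) -> None:
        """CSV with ``# key=value`` metadata header lines."""
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w") if own else path_or_buf
        try:
            fh.write(f"# x_kind={self.x_kind}\n")
            for k in sorted(self.metadata):
                fh.write(f"# {k}={self.metadata[k]}\n")
            cols = [self._COLUMNS[self.x_kind], "i_d_A"]
            extra = extra_columns or {}
            cols += list(extra)
            fh.write(",".join(cols) + "\n")
            for idx in range(len(self)):
                row = [f"{self.x[idx]:.10g}", f"{self.current[idx]:.10g}"]
                row += [f"{np.asarray(v)[idx]:.10g}" for v in extra.values()]
                fh.write(",".join(row) + "\n")
        finally:
            if own:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "ResponseCurve":
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf) if own else path_or_buf
        try:
            meta, rows, x_kind = {}, [], None
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    if key == "x_kind":
                        x_kind = val
                    else:
                        meta[key] = val
                    continue
                first = line.split(",")[0]
                try:
                    float(first)
                except ValueError:
                    continue  # header row
                parts = line.split(",")
                rows.append((float(parts[0]), float(parts[1])))
        finally:
            if own:
                fh.close()
        if x_kind is None or not rows:
            raise ValidationError("not a ResponseCurve CSV")
        x, i = (np.array(v) for v in zip(*rows))
        return cls(x, i, x_kind=x_kind, metadata=meta)
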