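"""Plot helpers for transfer, calibration and relative-response curves.

matplotlib is imported lazily so the simulation stack stays usable without
a plotting backend; all figures are written to file (Agg-safe).
"""

from __future__ import annotations

import numpy as np

from .curves import ResponseCurve
from .errors import ValidationError


def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4.2, 3.2), layout="constrained")
    return fig, ax


def plot_transfer(curve: ResponseCurve, path: str) -> None:
    """|I_D|–V_CG on a log current axis."""
    if curve.x_kind != "v_cg":
        raise ValidationError("expected a v_cg-indexed curve")
    fig, ax = _axes()
    ax.semilogy(curve.x, np.abs(curve.current), "o-", ms=3)
    ax.set_xlabel("$V_{CG}$ (V)")
    ax.set_ylabel("$|I_D|$ (A)")
    fig.savefig(path, dpi=150)
    _close(fig)


def plot_calibration(curve: ResponseCurve, path: str) -> None:
    """Drain current versus target concentration (log-x, c = 0 dropped)."""
    if curve.x_kind != "concentration":
        raise ValidationError("expected a concentration-indexed curve")
    mask = curve.x > 0
    fig, ax = _axes()
    ax.semilogx(curve.x[mask] * 1e9, np.abs(curve.current[mask]), "o-", ms=3)
    ax.set_xlabel("[T] (nM)")
    ax.set_ylabel("$|I_D|$ (A)")
    fig.savefig(path, dpi=150)
    _close(fig)


def plot_relative_response(curve: ResponseCurve, path: str) -> None:
    """ΔI/I₀ versus target concentration (log-x)."""
    if curve.x_kind != "concentration":
        raise ValidationError("expected a concentration-indexed curve")
    if curve.x[0] != 0.0:
        raise ValidationError("curve must include c = 0 as the baseline")
    i0 = curve.current[0]
    mask = curve.x > 0
    fig, ax = _axes()
    ax.semilogx(curve.x[mask] * 1e9,
                100.0 * (curve.current[mask] - i0) / i0, "o-", ms=3)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("[T] (nM)")
    ax.set_ylabel(r"$\Delta I / I_0$ (%)")
    fig.savefig(path, dpi=150)
    _close(fig)


def _close(fig) -> None:
    import matplotlib.pyplot as plt
    plt.close(fig)
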