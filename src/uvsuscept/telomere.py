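"""Telomere-content estimation from reads, and the qPCR calculators.

Telomere content is estimated two ways: a motif count (reads containing
seven or more consecutive copies of TTAGGG or its reverse complement)
and a GC-normalised content (the motif count divided by the number of
reads of comparable GC fraction, per million).  The qPCR side implements
the delta-delta-Cq telomere ratio with propagated standard errors, and
the UV interference percent-inhibition formula (1 - 2^-X) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import sem

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_MOTIF_RC = "CCCTAA"


@dataclass
class TelomereContentEstimate:
    telomeric_read_count: int
    total_reads: int
    method: str                      # "motif_count" or "gc_normalized"
    gc_window_read_count: int | None = None
    content_per_million: float | None = None


def count_telomeric_reads(reads: list[str], k: int = 7) -> TelomereContentEstimate:
    """Count reads containing >= k consecutive exact telomere motifs.

    A read qualifies iff ``(TTAGGG)^k`` or ``(CCCTAA)^k`` occurs as a
    contiguous substring (no mismatches).  Strand-symmetric: reverse
    complementing every read leaves the count unchanged.
    """
    fwd = TELOMERE_MOTIF * k
    rev = TELOMERE_MOTIF_RC * k
    n = sum(1 for r in reads if fwd in r.upper() or rev in r.upper())
    return TelomereContentEstimate(
        telomeric_read_count=n, total_reads=len(reads), method="motif_count"
    )


def gc_fraction(read: str) -> float:
    read = read.upper()
    denom = sum(read.count(b) for b in "ACGT")
    if denom == 0:
        return float("nan")
    return (read.count("G") + read.count("C")) / denom


def gc_normalized_content(
    reads: list[str],
    gc_window: tuple[float, float] = (0.48, 0.52),
    k: int = 7,
) -> TelomereContentEstimate:
    """Telomeric reads per million reads of comparable GC content.

    The telomere motif is GC-poor on one strand and GC-rich on the
    other; normalising by reads inside a fixed GC window removes
    library-size and GC-composition differences between samples.
    """
    if not reads:
        raise ValueError("no reads supplied")
    base = count_telomeric_reads(reads, k=k)
    lo, hi = gc_window
    in_window = sum(1 for r in reads if lo <= gc_fraction(r) <= hi)
    if in_window == 0:
        raise ValueError("no reads in the GC normalisation window")
    return TelomereContentEstimate(
        telomeric_read_count=base.telomeric_read_count,
        total_reads=len(reads),
        method="gc_normalized",
        gc_window_read_count=in_window,
        content_per_million=base.telomeric_read_count / in_window * 1e6,
    )


# -- qPCR -------------------------------------------------------------------

def _cell(panel: pd.DataFrame, target: str, condition: str) -> np.ndarray:
    cq = panel.loc[
        (panel["target"] == target) & (panel["condition"] == condition), "cq"
    ].to_numpy(dtype=float)
    if len(cq) == 0:
        raise ValueError(f"no Cq replicates for target={target!r}, condition={condition!r}")
    return cq


def qpcr_telomere_ratio(
    panel: pd.DataFrame,
    test_sample: str,
    ref_sample: str,
    telo_target: str = "telo",
    control_target: str = "36B4",
) -> tuple[float, float]:
    """Delta-delta-Cq telomere content fold change with propagated SE.

    ``dCq_s = mean Cq(telo, s) - mean Cq(control, s)``;
    ``ddCq = dCq_test - dCq_ref``; ``FC = 2^-ddCq``.  The SE of ddCq is
    the quadrature sum of the four cell SEMs, pushed through the
    exponential by the delta method: ``SE(FC) = FC * ln2 * SE(ddCq)``.
    """
    cells = {
        (t, s): _cell(panel, t, s)
        for t in (telo_target, control_target)
        for s in (test_sample, ref_sample)
    }
    d_test = cells[(telo_target, test_sample)].mean() - cells[(control_target, test_sample)].mean()
    d_ref = cells[(telo_target, ref_sample)].mean() - cells[(control_target, ref_sample)].mean()
    ddcq = d_test - d_ref
    se_ddcq = float(np.sqrt(sum(sem(c) ** 2 for c in cells.values())))
    fc = float(2.0 ** (-ddcq))
    return fc, fc * np.log(2) * se_ddcq


def percent_inhibition(
    panel: pd.DataFrame,
    target: str,
    control_target: str = "GAPDH",
    minus_uv: str = "-UV",
    plus_uv: str = "+UV",
) -> tuple[float, float]:
    """UV interference percent inhibition ``(1 - 2^-X) * 100`` with SE.

    ``D_c = mean Cq(control, c) - mean Cq(target, c)`` within each
    condition; ``X = D_-UV - D_+UV``.  UV lesions blocking amplification
    of the target raise its Cq in the +UV sample, giving X > 0 and
    positive inhibition (X = 1 -> 50%, X = 2 -> 75%).  SE comes from the
    quadrature sum of the four cell SEMs through the delta method
    (d/dX = 100 ln2 2^-X).
    """
    cells = {
        (t, c): _cell(panel, t, c)
        for t in (target, control_target)
        for c in (minus_uv, plus_uv)
    }
    d_minus = cells[(control_target, minus_uv)].mean() - cells[(target, minus_uv)].mean()
    d_plus = cells[(control_target, plus_uv)].mean() - cells[(target, plus_uv)].mean()
    x = d_minus - d_plus
    se_x = float(np.sqrt(sum(sem(c) ** 2 for c in cells.values())))
    inhibition = (1.0 - 2.0 ** (-x)) * 100.0
    se_inh = 100.0 * np.log(2) * 2.0 ** (-x) * se_x
    return float(inhibition), float(se_inh)
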