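"""Arithmetic of the minigene splicing-reporter readout.

From molar band quantities, proportion included I = inc/(inc+skip) and
proportion skipped S = 1 - I.  Skipping fitness relative to the no-insertion
construct is W_x = S_x / S_0, and the synergy index of a motif pair is

    SI = W_UD - W_U * W_D

SI < 0 means the pair suppresses skipping more than multiplicatively
(synergy in promoting inclusion); SI = 0 no synergy; SI > 0 anti-synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReporterMeasurement:
    construct: str
    included_molar: float
    skipped_molar: float

    def __post_init__(self) -> None:
        if self.included_molar < 0 or self.skipped_molar < 0:
            raise ValueError("band quantities must be non-negative")


def proportion_included(included_molar: float, skipped_molar: float) -> float:
    """I = included / (skipped + included) in molar quantities."""
    total = included_molar + skipped_molar
    if total <= 0:
        raise ValueError("included + skipped must be positive")
    return included_molar / total


def proportion_skipped(included_molar: float, skipped_molar: float) -> float:
    return 1.0 - proportion_included(included_molar, skipped_molar)


def intensity_to_molar(intensity: float, fragment_length: int) -> float:
    """Convert a stained-band intensity to a molar quantity: staining scales
    with mass, i.e. with fragment length, so molar ~ intensity / length."""
    if fragment_length <= 0:
        raise ValueError("fragment length must be positive")
    return intensity / fragment_length


@dataclass
class SynergyResult:
    s_0: float
    s_u: float
    s_d: float
    s_ud: float
    w_u: float
    w_d: float
    w_ud: float
    si: float
    classification: str  # "synergy" | "none" | "anti-synergy"


def synergy_index(
    s_0: float, s_u: float, s_d: float, s_ud: float, *, eps: float = 1e-12
) -> SynergyResult:
    """Synergy index from four skipping proportions (no-insertion, U-only,
    D-only, U+D).  |SI| < eps classifies as "none"."""
    for name, s in (("s_0", s_0), ("s_u", s_u), ("s_d", s_d), ("s_ud", s_ud)):
        if not 0 <= s <= 1:
            raise ValueError(f"{name} must be a proportion in [0, 1]")
    if s_0 == 0:
        raise ValueError("s_0 = 0: skipping fitness undefined")
    w_u, w_d, w_ud = s_u / s_0, s_d / s_0, s_ud / s_0
    si = w_ud - w_u * w_d
    if abs(si) < eps:
        cls = "none"
    elif si < 0:
        cls = "synergy"
    else:
        cls = "anti-synergy"
    return SynergyResult(s_0, s_u, s_d, s_ud, w_u, w_d, w_ud, si, cls)


def replicate_synergy(
    measurements: pd.DataFrame,
    *,
    baseline: str = "no-insertion",
    u_label: str = "U",
    d_label: str = "D",
    ud_label: str = "UD",
) -> pd.DataFrame:
    """Per-replicate synergy indices with mean +- SEM.

    ``measurements`` columns: construct, replicate, included_molar,
    skipped_molar.  SI is computed per transfection replicate (replicates are
    matched by label across constructs) so the reported SEM propagates
    replicate-level variability.
    """
    required = {"construct", "replicate", "included_molar", "skipped_molar"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    s = measurements.assign(
        s=[
            proportion_skipped(i, k)
            for i, k in zip(measurements["included_molar"], measurements["skipped_molar"])
        ]
    ).pivot_table(index="replicate", columns="construct", values="s")
    needed = [baseline, u_label, d_label, ud_label]
    missing = [c for c in needed if c not in s.columns]
    if missing:
        raise ValueError(f"missing constructs: {missing}")
    s = s.dropna(subset=needed)
    if s.empty:
        raise ValueError("no replicate has all four constructs")
    rows = []
    for rep, r in s.iterrows():
        res = synergy_index(r[baseline], r[u_label], r[d_label], r[ud_label])
        rows.append(dict(replicate=rep, si=res.si, classification=res.classification))
    out = pd.DataFrame(rows)
    out.attrs["si_mean"] = float(out["si"].mean())
    out.attrs["si_sem"] = (
        float(out["si"].std(ddof=1) / np.sqrt(len(out))) if len(out) > 1 else float("nan")
    )
    return out
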