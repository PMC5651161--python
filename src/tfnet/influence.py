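"""Relative influence of genes in a regulatory network.

The relative influence (RI) of a gene balances how many genes it regulates
against how many regulate it:

    RI = outDeg / (inDeg + outDeg)  -  (eps + inDeg) / (eps + outDeg)

where ``eps`` is a small positive constant guarding against division by
zero.  Unregulated hubs (inDeg = 0, large outDeg) score just below 1;
effector genes (outDeg = 0) score 0 after clipping; genes with many more
regulators than targets go negative and are clipped to 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .network import RegulatoryNetwork

__all__ = [
    "DEFAULT_EPSILON",
    "InfluenceConfig",
    "InfluenceRecord",
    "relative_influence",
    "clipped_influence",
    "influence_table",
    "top_bottom",
]

#: Default division guard; some curated prokaryotic tables are only
#: consistent with 1e-4 instead (see the methods note).
DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class InfluenceConfig:
    """Settings for an influence computation.

    epsilon : division guard, must be > 0 (default 1e-3).
    clip_negative : replace negative raw RI with 0 (default True).
    """

    epsilon: float = DEFAULT_EPSILON
    clip_negative: bool = True

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon!r}")


@dataclass(frozen=True)
class InfluenceRecord:
    """One row of an influence table: degrees plus (clipped) RI."""

    gene: str
    in_deg: int
    out_deg: int
    ri: float


def relative_influence(in_deg: int, out_deg: int, epsilon: float = DEFAULT_EPSILON) -> float:
    """Raw (unclipped) relative influence of a gene.

    The isolated-gene case inDeg = outDeg = 0 is defined as 0: a gene with
    neither regulators nor targets exerts no influence.

    >>> round(relative_influence(0, 2175, 1e-3), 8)
    0.99999954
    """
    if in_deg < 0 or out_deg < 0:
        raise ValueError(f"degrees must be non-negative, got ({in_deg}, {out_deg})")
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon!r}")
    if in_deg == 0 and out_deg == 0:
        return 0.0
    return out_deg / (in_deg + out_deg) - (epsilon + in_deg) / (epsilon + out_deg)


def clipped_influence(in_deg: int, out_deg: int, epsilon: float = DEFAULT_EPSILON) -> float:
    """Relative influence with negative values set to 0."""
    return max(0.0, relative_influence(in_deg, out_deg, epsilon))


def influence_table(net: RegulatoryNetwork, cfg: Optional[InfluenceConfig] = None) -> list[InfluenceRecord]:
    """Influence record for every gene, sorted by RI descending.

    Ties are broken by gene symbol ascending so tables are reproducible.
    """
    cfg = cfg or InfluenceConfig()
    records = []
    for d in net.degrees():
        ri = relative_influence(d.in_deg, d.out_deg, cfg.epsilon)
        if cfg.clip_negative and ri < 0:
            ri = 0.0
        records.append(InfluenceRecord(gene=d.gene, in_deg=d.in_deg, out_deg=d.out_deg, ri=ri))
    records.sort(key=lambda r: (-r.ri, r.gene))
    return records


def top_bottom(
    records: list[InfluenceRecord], k: int, restrict_to_tfs: bool = True
) -> tuple[list[InfluenceRecord], list[InfluenceRecord]]:
    """Top-k and bottom-k influence records.

    With ``restrict_to_tfs`` the zero-out-degree effectors are excluded
    *before* selection, so the bottom list shows the least influential
    transcription factors rather than a wall of zeros.  The bottom list is
    returned in ascending RI order.  ``k`` larger than the pool returns
    the whole pool.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    pool = [r for r in records if r.out_deg > 0] if restrict_to_tfs else list(records)
    pool.sort(key=lambda r: (-r.ri, r.gene))
    top = pool[:k]
    bottom = pool[-k:][::-1]
    return top, bottom
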