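"""Synthetic hierarchical regulatory networks with known ground truth.

Curated transcriptional networks share a three-tier hierarchy: a handful
of *master* TFs that nothing regulates transcriptionally, a larger layer
of regulated TFs, and a majority of *effector* genes that regulate
nothing.  Out-degrees are heavy-tailed (a few TFs control most genes),
edge weights are signed Z-score-like strengths, and the source database
may report several promoter-level records for one gene pair.

The generator emits an interaction-record stream with those features plus
a ground-truth manifest (tier, degrees, relative influence, polarity per
gene), so every downstream stage can be checked against known answers.
``as_provider`` wraps the same records as a mock gene-centric edge
database for exercising the breadth-first crawler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .influence import clipped_influence
from .network import RegulatoryNetwork, SignedInteraction
from .polarity import polarity_score

__all__ = [
    "GeneratorConfig",
    "ManifestRow",
    "generate",
    "as_provider",
    "MockEdgeProvider",
    "write_manifest",
]

#: Z-score dynamic range of curated interaction strengths.
WEIGHT_MIN, WEIGHT_MAX = -10.0, 12.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic network.

    n_master / n_tf / n_effector : tier sizes (masters have in-degree 0,
        effectors out-degree 0).
    out_degree_exponent : power-law tail exponent for TF out-degrees;
        2.0 gives the "few TFs control most genes" profile.
    max_out_degree : cap on drawn out-degrees (default: all possible
        targets, i.e. n_tf + n_effector).
    activator_bias : (a, b) of a Beta prior on each TF's fraction of
        positive (activating) outgoing edges; (2, 2) centres TFs on a
        balanced mix while allowing strong overall activators/repressors.
    weight_scale : scale of the half-normal magnitude distribution for
        |weight|; samples are truncated to the Z-score range [-10, 12].
    duplicate_rate : probability that an edge also emits 1-3 extra
        promoter-level records with weights below the primary record, so
        max-aggregation recovers the primary exactly.
    mixed_sign_duplicates : allow duplicate records whose sign differs
        from the primary (still below it in signed value); off by default.
    manifest_epsilon : epsilon at which the manifest's true RI is stated.
    seed : PRNG seed; identical config + seed reproduce the stream and
        manifest byte for byte.
    """

    n_master: int
    n_tf: int
    n_effector: int
    out_degree_exponent: float = 2.0
    max_out_degree: Optional[int] = None
    activator_bias: tuple[float, float] = (2.0, 2.0)
    weight_scale: float = 2.0
    duplicate_rate: float = 0.2
    mixed_sign_duplicates: bool = False
    manifest_epsilon: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_master, self.n_tf, self.n_effector) < 0:
            raise ValueError("tier sizes must be non-negative")
        if self.n_effector > 0 and self.n_master + self.n_tf < 1:
            raise ValueError("effectors require at least one regulating TF tier gene")
        if self.n_tf > 0 and self.n_master + self.n_tf < 2:
            raise ValueError(
                "a regulated TF needs a possible regulator other than itself: "
                "require n_master + n_tf >= 2 when n_tf >= 1"
            )
        if self.out_degree_exponent <= 1.0:
            raise ValueError("out_degree_exponent must exceed 1")
        if not (0.0 <= self.duplicate_rate <= 1.0):
            raise ValueError("duplicate_rate must be in [0, 1]")
        a, b = self.activator_bias
        if a <= 0 or b <= 0:
            raise ValueError("activator_bias parameters must be positive")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")


@dataclass(frozen=True)
class ManifestRow:
    """Ground truth for one gene, stated post-aggregation."""

    gene: str
    tier: str  # master | tf | effector
    in_degree: int
    out_degree: int
    ri_true: float
    polarity_true: float  # sign-mode score


def _power_law_degree(rng: np.random.Generator, gamma: float, k_max: int) -> int:
    """Draw from P(k) ∝ k^-gamma on {1..k_max} by inverse CDF."""
    if k_max < 1:
        return 0
    k = np.arange(1, k_max + 1, dtype=float)
    p = k ** (-gamma)
    p /= p.sum()
    return int(rng.choice(k_max, p=p)) + 1


def _draw_magnitude(rng: np.random.Generator, scale: float, positive: bool) -> float:
    """Half-normal |weight|, truncated to the Z-score dynamic range."""
    cap = WEIGHT_MAX if positive else -WEIGHT_MIN
    while True:
        m = abs(rng.normal(0.0, scale))
        if 0 < m <= cap:
            return m


def _quantize(w: float) -> float:
    # emitted weights carry 9 significant digits, like the edge-TSV dialect,
    # so a write -> read round trip is exact
    return float(format(w, ".9g"))


def generate(cfg: GeneratorConfig) -> tuple[list[SignedInteraction], list[ManifestRow]]:
    """Generate an interaction-record stream plus its ground-truth manifest.

    Masters receive no incoming edges; effectors emit none; every
    regulated TF and every effector has at least one regulator.  Each
    edge's primary weight is signed by its source TF's activator fraction;
    duplicate promoter-level records never exceed the primary, so the
    bulk-loaded (max-aggregated) network matches the manifest exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    masters = [f"M{i+1:03d}" for i in range(cfg.n_master)]
    tfs = [f"T{i+1:03d}" for i in range(cfg.n_tf)]
    effectors = [f"E{i+1:03d}" for i in range(cfg.n_effector)]
    sources = masters + tfs

    # --- topology: one target set per source ------------------------------
    edge_targets: dict[str, list[str]] = {}
    for src in sources:
        pool = [t for t in tfs + effectors if t != src]
        if not pool:
            edge_targets[src] = []
            continue
        k_cap = len(pool) if cfg.max_out_degree is None else min(cfg.max_out_degree, len(pool))
        d = _power_law_degree(rng, cfg.out_degree_exponent, k_cap)
        picked = rng.choice(len(pool), size=d, replace=False)
        edge_targets[src] = [pool[i] for i in sorted(picked)]

    # every regulated TF / effector needs >=1 regulator
    regulated = {t for targets in edge_targets.values() for t in targets}
    for orphan in tfs + effectors:
        if orphan in regulated:
            continue
        candidates = [s for s in sources if s != orphan]
        src = candidates[int(rng.integers(len(candidates)))]
        edge_targets[src] = sorted(edge_targets[src] + [orphan])

    # --- weights, duplicates ---------------------------------------------
    a, b = cfg.activator_bias
    records: list[SignedInteraction] = []
    primary_weight: dict[tuple[str, str], float] = {}
    for src in sources:
        p_act = float(rng.beta(a, b))
        for tgt in edge_targets[src]:
            positive = bool(rng.random() < p_act)
            mag = _draw_magnitude(rng, cfg.weight_scale, positive)
            w = _quantize(mag if positive else -mag)
            primary_weight[(src, tgt)] = w
            records.append(SignedInteraction(source=src, target=tgt, weight=w, promoter_id=f"{tgt}.p1"))
            if cfg.duplicate_rate > 0 and rng.random() < cfg.duplicate_rate:
                n_dup = int(rng.integers(1, 4))
                for j in range(n_dup):
                    if cfg.mixed_sign_duplicates:
                        lo = WEIGHT_MIN
                    else:
                        lo = 0.0 if w > 0 else WEIGHT_MIN
                    dup = min(_quantize(float(rng.uniform(lo, w))), w)
                    records.append(
                        SignedInteraction(source=src, target=tgt, weight=dup, promoter_id=f"{tgt}.p{j+2}")
                    )

    # --- ground-truth manifest (post-aggregation degrees) -----------------
    in_deg = {g: 0 for g in masters + tfs + effectors}
    out_deg = {g: 0 for g in masters + tfs + effectors}
    pos_out = {g: 0 for g in masters + tfs + effectors}
    neg_out = {g: 0 for g in masters + tfs + effectors}
    for (s, t), w in primary_weight.items():
        out_deg[s] += 1
        in_deg[t] += 1
        if w > 0:
            pos_out[s] += 1
        elif w < 0:
            neg_out[s] += 1
    tier = {g: "master" for g in masters}
    tier.update({g: "tf" for g in tfs})
    tier.update({g: "effector" for g in effectors})
    manifest = [
        ManifestRow(
            gene=g,
            tier=tier[g],
            in_degree=in_deg[g],
            out_degree=out_deg[g],
            ri_true=clipped_influence(in_deg[g], out_deg[g], cfg.manifest_epsilon),
            polarity_true=float(pos_out[g] - neg_out[g]),
        )
        for g in masters + tfs + effectors
    ]
    return records, manifest


class MockEdgeProvider:
    """In-memory gene-centric edge database over a record stream.

    Answers ``regulators_of`` / ``targets_of`` from the records, duplicate
    promoter-level entries included, outputs lexicographically sorted.
    Query counts are tallied in ``calls`` for call-budget audits.
    """

    def __init__(self, records: list[SignedInteraction]):
        self._in: dict[str, list[tuple[str, float]]] = {}
        self._out: dict[str, list[tuple[str, float]]] = {}
        for rec in records:
            self._in.setdefault(rec.source, [])
            self._out.setdefault(rec.target, [])
            self._in.setdefault(rec.target, []).append((rec.source, rec.weight))
            self._out.setdefault(rec.source, []).append((rec.target, rec.weight))
        for d in (self._in, self._out):
            for gene in d:
                d[gene].sort()
        self.calls: dict[str, int] = {}

    def symbols(self) -> list[str]:
        return sorted(self._in)

    def regulators_of(self, gene: str) -> list[tuple[str, float]]:
        self.calls[gene] = self.calls.get(gene, 0) + 1
        return list(self._in.get(gene, []))

    def targets_of(self, gene: str) -> list[tuple[str, float]]:
        self.calls[gene] = self.calls.get(gene, 0) + 1
        return list(self._out.get(gene, []))


def as_provider(records: list[SignedInteraction]) -> MockEdgeProvider:
    """Wrap generated records as a mock edge database for the crawler."""
    return MockEdgeProvider(records)


def write_manifest(manifest: list[ManifestRow], path) -> None:
    """Manifest TSV: gene, tier, in_degree, out_degree, ri_true, polarity_true."""
    lines = ["gene\ttier\tin_degree\tout_degree\tri_true\tpolarity_true"]
    for row in manifest:
        lines.append(
            f"{row.gene}\t{row.tier}\t{row.in_degree}\t{row.out_degree}"
            f"\t{format(row.ri_true, '.9g')}\t{format(row.polarity_true, '.9g')}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def verify_manifest(records: list[SignedInteraction], manifest: list[ManifestRow],
                    epsilon: float = 1e-3) -> None:
    """Cross-check manifest ground truth against the bulk-loaded network.

    Raises AssertionError on any disagreement; used by the generator's own
    tests and available to users who tweak the configuration.
    """
    net = RegulatoryNetwork.from_interactions(records)
    degs = {d.gene: d for d in net.degrees()}
    for row in manifest:
        d = degs.get(row.gene)
        if d is None:
            assert row.in_degree == 0 and row.out_degree == 0, f"{row.gene}: missing but has degrees"
            continue
        assert (d.in_deg, d.out_deg) == (row.in_degree, row.out_degree), (
            f"{row.gene}: manifest degrees {(row.in_degree, row.out_degree)} "
            f"!= network {(d.in_deg, d.out_deg)}"
        )
        if row.tier == "master":
            assert d.in_deg == 0, f"master {row.gene} has regulators"
        if row.tier == "effector":
            assert d.out_deg == 0, f"effector {row.gene} has targets"
        ri = clipped_influence(d.in_deg, d.out_deg, epsilon)
        assert abs(ri - row.ri_true) < 1e-12, f"{row.gene}: RI mismatch"
        if d.out_deg > 0:
            pol = polarity_score(net, row.gene, mode="sign").score
            assert pol == row.polarity_true, f"{row.gene}: polarity mismatch"
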