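"""Overall activator/repressor classification of transcription factors.

Each outgoing edge of a TF either activates (weight > 0) or represses
(weight < 0) its target; weight-0 ("dual") edges are neutral.  Summing
over all targets gives an algebraic score whose sign classifies the TF:

* sign mode (default): score = #positive targets - #negative targets;
* weight mode: score = sum of raw edge weights.

A positive score makes the TF an *overall activator*, a negative one an
*overall repressor*; the two modes can disagree when a few strong edges
oppose many weak ones.  These labels are phenotype- and context-dependent
summaries of one network, not intrinsic protein properties.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import RegulatoryNetwork, UnknownGeneError

__all__ = ["PolarityScore", "polarity_score", "polarity_table", "MODES"]

MODES = ("sign", "weight")


@dataclass(frozen=True)
class PolarityScore:
    gene: str
    n_positive: int
    n_negative: int
    n_neutral: int
    score: float
    label: str  # overall_activator | overall_repressor | neutral


def _label(score: float) -> str:
    if score > 0:
        return "overall_activator"
    if score < 0:
        return "overall_repressor"
    return "neutral"


def polarity_score(net: RegulatoryNetwork, gene: str, mode: str = "sign") -> PolarityScore:
    """Algebraic polarity of one gene over its outgoing edges only."""
    if mode not in MODES:
        raise ValueError(f"unknown polarity mode {mode!r}; expected one of {MODES}")
    if gene not in net:
        raise UnknownGeneError(gene)
    n_pos = n_neg = n_neu = 0
    wsum = 0.0
    for _t, w in net.out_edges(gene):
        if w > 0:
            n_pos += 1
        elif w < 0:
            n_neg += 1
        else:
            n_neu += 1
        wsum += w
    score = float(n_pos - n_neg) if mode == "sign" else wsum
    return PolarityScore(
        gene=gene, n_positive=n_pos, n_negative=n_neg, n_neutral=n_neu,
        score=score, label=_label(score),
    )


def polarity_table(net: RegulatoryNetwork, mode: str = "sign") -> list[PolarityScore]:
    """One polarity score per TF (out-degree > 0), best activators first.

    Sorted by score descending, ties by gene symbol; the head of the list
    holds the strongest overall activators and the tail the strongest
    overall repressors.
    """
    if mode not in MODES:
        raise ValueError(f"unknown polarity mode {mode!r}; expected one of {MODES}")
    counts: dict[str, list] = {}
    for s, t, w in net.edges():
        c = counts.setdefault(s, [0, 0, 0, 0.0])
        if w > 0:
            c[0] += 1
        elif w < 0:
            c[1] += 1
        else:
            c[2] += 1
        c[3] += w
    scores = []
    for gene, (n_pos, n_neg, n_neu, wsum) in counts.items():
        score = float(n_pos - n_neg) if mode == "sign" else wsum
        scores.append(PolarityScore(gene, n_pos, n_neg, n_neu, score, _label(score)))
    scores.sort(key=lambda p: (-p.score, p.gene))
    return scores
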