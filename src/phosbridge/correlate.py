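"""Score protonation hypotheses against observed ECD coverage.

A noncovalent contact that survives electron capture holds the two
fragments together, so cleavages between the bound residues produce no
separated fragments.  Each hypothesis' interaction matrix therefore
predicts a set of suppressed cleavage sites; comparing predicted
observability with the measured coverage map (fragments present vs
absent per site) gives a per-site agreement score in [0, 1], and the
hypotheses are ranked by it.  The score formalizes the qualitative
model-vs-experiment comparison; it is a design choice of this package,
not a literature statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fragments import CoverageMap
from .interactions import InteractionMatrix, ProtonationPattern

#: contact classifications treated as strong enough to survive ECD.
DEFAULT_SUPPRESSING = frozenset({"salt_bridge", "ionic_hydrogen_bond"})


def suppressed_sites(pairs: list[tuple[int, int]], n_residues: int) -> set[int]:
    """Cleavage sites whose products would separate any bound pair.

    For a contact between residues ``a < b`` these are the sites
    ``a <= s < b``; the result is the union over all pairs.
    """
    out: set[int] = set()
    for a, b in pairs:
        if not 1 <= a < b <= n_residues:
            raise ValueError(f"invalid pair ({a}, {b}) for N={n_residues}")
        out.update(range(a, b))
    return out


@dataclass
class SuppressionPrediction:
    """Sites predicted unobservable under one protonation hypothesis."""

    hypothesis: str
    n_residues: int
    per_structure: dict[str, set[int]]
    suppressed: set[int]
    rule: str

    @property
    def observable(self) -> set[int]:
        return set(range(1, self.n_residues)) - self.suppressed


def predict(
    matrix: InteractionMatrix,
    n_residues: int,
    rule: str = "union",
    suppressing: frozenset[str] = DEFAULT_SUPPRESSING,
) -> SuppressionPrediction:
    """Turn an interaction matrix into a suppressed-site prediction.

    Only contacts whose classification is in ``suppressing`` count.
    ``rule`` aggregates over structures: "union" (any structure's
    contact suppresses) or "majority" (more than half the structures
    must share the contact).
    """
    if rule not in ("union", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    pattern = matrix.pattern
    site_res = {s.name: s.residue for s in pattern.sites}
    per_structure: dict[str, set[int]] = {s: set() for s in matrix.structures}
    pair_votes: dict[tuple[int, int], int] = {}
    for rec in matrix.records:
        if rec.contact and rec.classification in suppressing:
            a, b = sorted((pattern.phosphosite, site_res[rec.site]))
            per_structure[rec.structure] |= suppressed_sites([(a, b)], n_residues)
            pair_votes[(a, b)] = pair_votes.get((a, b), 0) + 1
    n_struct = len(matrix.structures)
    if rule == "union":
        pairs = list(pair_votes)
    else:
        pairs = [p for p, v in pair_votes.items() if v > n_struct / 2]
    return SuppressionPrediction(
        pattern.name,
        n_residues,
        per_structure,
        suppressed_sites(pairs, n_residues),
        rule,
    )


@dataclass
class AgreementScore:
    """Per-site agreement between a prediction and observed coverage."""

    hypothesis: str
    matches: int
    n_sites: int
    per_site: dict[int, bool]

    @property
    def score(self) -> float:
        return self.matches / self.n_sites


def score(pred: SuppressionPrediction, cov: CoverageMap) -> AgreementScore:
    """Fraction of cleavage sites where prediction matches observation.

    A site agrees when it is predicted observable and carries at least
    one assigned fragment, or predicted suppressed and carries none.
    """
    if pred.n_residues != cov.n_residues:
        raise ValueError(
            f"peptide length mismatch ({pred.n_residues} vs {cov.n_residues})"
        )
    per_site = {}
    for s in range(1, cov.n_residues):
        observed = cov.count_at(s) > 0
        predicted_observable = s in pred.observable
        per_site[s] = observed == predicted_observable
    matches = sum(per_site.values())
    return AgreementScore(pred.hypothesis, matches, cov.n_residues - 1, per_site)


def rank_hypotheses(
    scores: list[AgreementScore],
) -> list[tuple[AgreementScore, bool]]:
    """Scores in descending order; the flag marks ties with a neighbor."""
    if not scores:
        raise ValueError("no scores to rank")
    ordered = sorted(scores, key=lambda a: -a.score)
    flags = []
    for i, sc in enumerate(ordered):
        tied = (i > 0 and ordered[i - 1].score == sc.score) or (
            i + 1 < len(ordered) and ordered[i + 1].score == sc.score
        )
        flags.append((sc, tied))
    return flags
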