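"""Cross-annotation of discriminative MSI m/z values against LC-MS/MS peptides.

A bottom-up LC-MS/MS run on adjacent tissue supplies a reference list of
tryptic peptide monoisotopic masses with their parent proteins.  Each
discriminative MSI m/z value is matched to the reference peptide with the
smallest absolute mass difference, accepted only below a tolerance
(default 0.2 Da).  A protein is then assigned only under the two-peptide
concordance rule: at least ``min_peptides`` distinct MSI m/z values must match
peptides of that protein, and their differential directions (intensity up or
down in the feature-positive group, i.e. AUC above or below 0.5) must agree.

Deviations are reported signed, convention ``msi_mz - ref_mass``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .discrim import DiscriminativeFeature

__all__ = [
    "ReferencePeptide",
    "PeptideMatch",
    "ProteinAssignment",
    "mass_delta",
    "match_to_reference",
    "infer_proteins",
]


@dataclass(frozen=True)
class ReferencePeptide:
    """One LC-MS/MS reference entry: peptide monoisotopic mass and parent protein."""

    mass: float
    protein: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"reference mass must be positive, got {self.mass}")


@dataclass
class PeptideMatch:
    """A discriminative MSI m/z paired with its nearest reference peptide."""

    msi_mz: float
    ref: ReferencePeptide
    delta: float  # signed, msi_mz - ref.mass
    auc: float
    direction: str  # "up" | "down"
    feature: str | None = None


@dataclass
class ProteinAssignment:
    """A protein supported by >= 2 direction-concordant peptide matches."""

    protein: str
    matches: list[PeptideMatch]
    direction: str  # "up" | "down" | "mixed" (only without the concordance rule)
    feature: str | None = None

    def __post_init__(self) -> None:
        if len({m.msi_mz for m in self.matches}) < 2:
            raise ValueError(f"protein {self.protein!r}: needs >= 2 distinct m/z matches")
        if self.direction != "mixed" and any(
            m.direction != self.direction for m in self.matches
        ):
            raise ValueError(f"protein {self.protein!r}: discordant match directions")

    @property
    def msi_mzs(self) -> list[float]:
        return [m.msi_mz for m in self.matches]


def mass_delta(msi_mz: float, ref_mass: float) -> float:
    """Signed mass deviation of an MSI centroid from a reference peptide mass."""
    if not (msi_mz > 0 and ref_mass > 0):
        raise ValueError("masses must be positive")
    return msi_mz - ref_mass


def match_to_reference(
    disc: "list[DiscriminativeFeature]",
    ref: list[ReferencePeptide],
    tolerance: float = 0.2,
) -> list[PeptideMatch]:
    """Match each discriminative m/z to its nearest reference peptide.

    The reference peptide with the smallest ``|msi_mz - mass|`` is selected iff
    the absolute deviation is strictly below ``tolerance``; m/z values with no
    reference inside the tolerance are left unmatched (omitted).  Ties on the
    absolute deviation are broken by the lexicographically smaller protein
    name, so matching is deterministic.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    matches: list[PeptideMatch] = []
    for d in disc:
        if not ref:
            break
        best = min(ref, key=lambda r: (abs(mass_delta(d.mz, r.mass)), r.protein))
        delta = mass_delta(d.mz, best.mass)
        if abs(delta) < tolerance:
            matches.append(
                PeptideMatch(
                    msi_mz=d.mz,
                    ref=best,
                    delta=delta,
                    auc=d.auc,
                    direction=d.direction,
                    feature=getattr(d, "feature", None),
                )
            )
    return matches


def infer_proteins(
    matches: list[PeptideMatch],
    min_peptides: int = 2,
    require_concordance: bool = True,
) -> list[ProteinAssignment]:
    """Apply the two-peptide concordance rule to peptide matches.

    Matches are grouped by protein; a :class:`ProteinAssignment` is emitted iff
    at least ``min_peptides`` distinct MSI m/z values match the protein and
    (when ``require_concordance``) all matches share one differential
    direction.  Output is sorted by protein name, so it is invariant to the
    input order.
    """
    by_protein: dict[str, list[PeptideMatch]] = {}
    for m in matches:
        by_protein.setdefault(m.ref.protein, []).append(m)
    out: list[ProteinAssignment] = []
    for protein in sorted(by_protein):
        group = sorted(by_protein[protein], key=lambda m: m.msi_mz)
        distinct = {m.msi_mz for m in group}
        if len(distinct) < min_peptides:
            continue
        directions = {m.direction for m in group}
        if require_concordance and len(directions) > 1:
            continue
        out.append(
            ProteinAssignment(
                protein=protein,
                matches=group,
                direction=group[0].direction if len(directions) == 1 else "mixed",
                feature=group[0].feature,
            )
        )
    return out
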