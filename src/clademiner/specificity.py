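"""Clade-specificity calls for subfamilies and class-count summaries.

A subfamily is clade-specific when every member belongs to a species of
the declared ingroup; a single outgroup member flips it to shared. Because
specificity is relative to the sampled outgroup, every summary carries a
caveat string: apparently clade-specific subfamilies may simply be missing
from the (finite) outgroup sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phylo import SubfamilyAssignment

__all__ = ["SpecificityCall", "ClassCounts", "call_clade_specific", "specificity_summary"]

OUTGROUP_CAVEAT = (
    "Clade-specificity is relative to the sampled outgroup: a subfamily "
    "called specific here may occur in unsampled species outside the "
    "ingroup; the true clade-specific set is likely a subset of the "
    "called one."
)


@dataclass
class SpecificityCall:
    subfamily_id: str
    specific: bool
    ingroup_species_present: int
    outgroup_species_present: int

    def __post_init__(self) -> None:
        # specific requires zero outgroup species; the converse may be
        # vetoed by a min_ingroup_species requirement
        if self.specific and self.outgroup_species_present > 0:
            raise ValueError("specific flag inconsistent with outgroup presence")


@dataclass
class ClassCounts:
    """Counts of specific/shared subfamilies and genes for a focal species.

    Subfamily counts cover subfamilies containing the focal species; gene
    counts cover the focal species' superfamily members.
    """

    n_specific_subfamilies: int
    n_shared_subfamilies: int
    n_specific_genes_focal: int
    n_shared_genes_focal: int
    focal_species: str
    caveat: str = OUTGROUP_CAVEAT

    @property
    def n_genes_focal(self) -> int:
        return self.n_specific_genes_focal + self.n_shared_genes_focal

    @property
    def n_subfamilies_focal(self) -> int:
        return self.n_specific_subfamilies + self.n_shared_subfamilies


def call_clade_specific(
    assignment: SubfamilyAssignment,
    ingroup: set[str],
    species_universe: set[str] | None = None,
    min_ingroup_species: int = 1,
) -> list[SpecificityCall]:
    """One call per subfamily: specific iff all member species lie in the
    ingroup (and at least ``min_ingroup_species`` distinct ingroup species
    are present; default 1, i.e. single-species private subfamilies count).
    """
    if not ingroup:
        raise ValueError("ingroup must be non-empty")
    ingroup = set(ingroup)
    calls: list[SpecificityCall] = []
    for sf_id in assignment.subfamily_ids:
        species = assignment.species_multiset(sf_id)
        if species_universe is not None:
            unknown = set(species) - set(species_universe)
            if unknown:
                raise ValueError(
                    f"subfamily {sf_id}: species outside declared universe: "
                    f"{sorted(unknown)}"
                )
        n_in = len({s for s in species if s in ingroup})
        n_out = len({s for s in species if s not in ingroup})
        calls.append(
            SpecificityCall(
                subfamily_id=sf_id,
                specific=(n_out == 0 and n_in >= min_ingroup_species),
                ingroup_species_present=n_in,
                outgroup_species_present=n_out,
            )
        )
    return calls


def specificity_summary(
    calls: list[SpecificityCall],
    assignment: SubfamilyAssignment,
    focal_species: str,
) -> ClassCounts:
    """Class counts restricted to one focal species, with the conservation
    invariants asserted (gene counts sum to the focal superfamily total;
    subfamily counts sum to the focal subfamily total)."""
    focal_genes = [g for g, sp in assignment.species_of.items() if sp == focal_species]
    if not focal_genes:
        raise ValueError(f"focal species {focal_species!r} not present in any subfamily")
    specific_sf = {c.subfamily_id for c in calls if c.specific}

    n_spec_sf = n_shared_sf = n_spec_genes = n_shared_genes = 0
    for sf_id in assignment.subfamily_ids:
        genes_here = [
            g for g in assignment.members[sf_id]
            if assignment.species_of[g] == focal_species
        ]
        if not genes_here:
            continue
        if sf_id in specific_sf:
            n_spec_sf += 1
            n_spec_genes += len(genes_here)
        else:
            n_shared_sf += 1
            n_shared_genes += len(genes_here)

    counts = ClassCounts(
        n_specific_subfamilies=n_spec_sf,
        n_shared_subfamilies=n_shared_sf,
        n_specific_genes_focal=n_spec_genes,
        n_shared_genes_focal=n_shared_genes,
        focal_species=focal_species,
    )
    assert counts.n_genes_focal == len(focal_genes)
    n_sf_focal = sum(
        1
        for sf_id in assignment.subfamily_ids
        if any(assignment.species_of[g] == focal_species for g in assignment.members[sf_id])
    )
    assert counts.n_subfamilies_focal == n_sf_focal
    return counts
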