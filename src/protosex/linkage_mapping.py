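"""Pedigree recombinant screening and refinement of the sex-locus interval.

The workflow mirrors classic fine-mapping of an XY locus in F1 families:
phase the father's X and Y haplotypes against nonrecombinant offspring,
screen offspring whose transmitted paternal type switches between two
flanking markers, then intersect recombinant breakpoints with phenotypic sex
to exclude map positions and delimit the candidate interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_model import GenotypeMatrix, Interval, Marker

__all__ = [
    "PaternalPhase",
    "TransmittedHaplotype",
    "RecombinantReport",
    "RefineResult",
    "PhaseUndeterminedError",
    "NoIntervalError",
    "infer_paternal_phase",
    "transmitted_types",
    "find_recombinants",
    "refine_sd_interval",
]

UNINFORMATIVE = "uninformative"


class PhaseUndeterminedError(RuntimeError):
    """The father's X/Y haplotypes cannot be resolved from this family."""


class NoIntervalError(RuntimeError):
    """Every marker is excluded; genotype or phenotype data are inconsistent."""


@dataclass
class PaternalPhase:
    """Father's X-type and Y-type alleles per marker (None = uninformative)."""

    x_allele: dict[str, str | None]
    y_allele: dict[str, str | None]

    def informative_markers(self) -> list[str]:
        return [
            mid
            for mid, x in self.x_allele.items()
            if x is not None and self.y_allele[mid] is not None
        ]


@dataclass
class TransmittedHaplotype:
    """Per-offspring paternal type along the map."""

    offspring_id: str
    #: per-marker "X", "Y" or "uninformative", aligned with the marker order
    labels: list[str]
    #: adjacent informative marker pairs between which the label switches
    crossover_intervals: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class RecombinantReport:
    recombinant_ids: list[str]
    haplotypes: dict[str, TransmittedHaplotype]
    n_screened: int
    uninformative_ids: list[str]
    markers: list[Marker]
    sexes: dict[str, str]


@dataclass
class RefineResult:
    intervals: list[Interval]
    ambiguous: bool
    #: per marker id: number of offspring whose type contradicts their sex
    mismatches: dict[str, int]

    @property
    def interval(self) -> Interval:
        """The widest candidate interval (ties: leftmost)."""
        return max(self.intervals, key=lambda iv: (iv.length_bp, -iv.start_bp))


# ---------------------------------------------------------------------------
# Paternal allele resolution
# ---------------------------------------------------------------------------

def _paternal_allele(
    offspring_g, father_g, mother_g
) -> str | None:
    """Which of the father's alleles was transmitted, if resolvable.

    Returns None when the father is homozygous, any genotype is missing, or
    both paternal alleles are consistent with the offspring genotype given
    the mother.
    """
    if offspring_g is None or father_g is None or mother_g is None:
        return None
    if father_g[0] == father_g[1]:
        return None
    candidates = set()
    for p in set(father_g):
        for m in set(mother_g):
            if tuple(sorted((p, m))) == offspring_g:
                candidates.add(p)
    if len(candidates) == 1:
        return candidates.pop()
    return None


def _family_roles(family: GenotypeMatrix):
    father = mother = None
    offspring = []
    for i, ind in enumerate(family.individuals):
        if ind.role == "father":
            father = i
        elif ind.role == "mother":
            mother = i
        elif ind.role == "offspring":
            offspring.append(i)
    if father is None:
        raise PhaseUndeterminedError("father not genotyped in this family")
    if not offspring:
        raise PhaseUndeterminedError("no offspring in this family")
    return father, mother, offspring


def infer_paternal_phase(
    family: GenotypeMatrix, anchor_marker: str
) -> PaternalPhase:
    """Resolve the father's X and Y haplotypes from offspring transmissions.

    At the anchor marker (the causal marker or its closest proxy) the
    paternal allele transmitted to the majority of male offspring is labelled
    Y-type and to the majority of females X-type.  Every other marker is then
    phased by majority vote over offspring typed at the anchor, choosing
    between the two possible phase assignments (the allele co-transmitted
    with anchor-Y gametes is Y-type).  Markers where the father is
    homozygous or the vote ties are flagged uninformative.
    """
    f_idx, m_idx, off_idx = _family_roles(family)
    anchor_j = family.marker_index(anchor_marker)
    father_g = family.genotypes[f_idx]
    mother_g = (
        family.genotypes[m_idx]
        if m_idx is not None
        else [None] * family.n_markers
    )
    if father_g[anchor_j] is None or father_g[anchor_j][0] == father_g[anchor_j][1]:
        raise PhaseUndeterminedError(
            f"father is not heterozygous at anchor marker {anchor_marker}"
        )

    # anchor typing: allele transmitted to most males = Y, to most females = X
    votes: dict[str, dict[str, int]] = {"male": {}, "female": {}}
    anchor_allele: dict[int, str] = {}
    for i in off_idx:
        allele = _paternal_allele(
            family.genotypes[i][anchor_j], father_g[anchor_j], mother_g[anchor_j]
        )
        if allele is None:
            continue
        anchor_allele[i] = allele
        sex = family.individuals[i].sex
        if sex in votes:
            votes[sex][allele] = votes[sex].get(allele, 0) + 1

    def majority(counts: dict[str, int]) -> str | None:
        if not counts:
            return None
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(best) > 1 and best[0][1] == best[1][1]:
            return None
        return best[0][0]

    y_anchor = majority(votes["male"])
    x_anchor = majority(votes["female"])
    alleles = set(father_g[anchor_j])
    if y_anchor is None and x_anchor is not None:
        y_anchor = (alleles - {x_anchor}).pop()
    if x_anchor is None and y_anchor is not None:
        x_anchor = (alleles - {y_anchor}).pop()
    if y_anchor is None or x_anchor is None or y_anchor == x_anchor:
        raise PhaseUndeterminedError(
            "cannot type the anchor marker: need nonrecombinant offspring of "
            "each sex with resolvable transmission"
        )

    # per-offspring anchor type
    anchor_type = {
        i: ("Y" if a == y_anchor else "X") for i, a in anchor_allele.items()
    }

    x_allele: dict[str, str | None] = {}
    y_allele: dict[str, str | None] = {}
    n_informative = 0
    for j, marker in enumerate(family.markers):
        if j == anchor_j:
            x_allele[marker.id] = x_anchor
            y_allele[marker.id] = y_anchor
            n_informative += 1
            continue
        fg = father_g[j]
        if fg is None or fg[0] == fg[1]:
            x_allele[marker.id] = None
            y_allele[marker.id] = None
            continue
        a, b = fg
        # vote between the two phase assignments: "Y carries a" gains a
        # point from every anchor-Y gamete carrying a and every anchor-X
        # gamete carrying b (and symmetrically for "Y carries b")
        score_a = score_b = 0
        for i, t in anchor_type.items():
            allele = _paternal_allele(
                family.genotypes[i][j], fg, mother_g[j]
            )
            if allele is None:
                continue
            if (allele == a) == (t == "Y"):
                score_a += 1
            else:
                score_b += 1
        if score_a == score_b:
            x_allele[marker.id] = None
            y_allele[marker.id] = None
        else:
            y_m, x_m = (a, b) if score_a > score_b else (b, a)
            x_allele[marker.id] = x_m
            y_allele[marker.id] = y_m
            n_informative += 1
    if n_informative <= 1 and family.n_markers > 1:
        raise PhaseUndeterminedError(
            "phase undetermined: no marker beyond the anchor could be phased"
        )
    return PaternalPhase(x_allele, y_allele)


def transmitted_types(
    family: GenotypeMatrix, phase: PaternalPhase
) -> dict[str, TransmittedHaplotype]:
    """Label each offspring's transmitted paternal type at every marker."""
    f_idx, m_idx, off_idx = _family_roles(family)
    father_g = family.genotypes[f_idx]
    mother_g = (
        family.genotypes[m_idx]
        if m_idx is not None
        else [None] * family.n_markers
    )
    out: dict[str, TransmittedHaplotype] = {}
    for i in off_idx:
        labels: list[str] = []
        for j, marker in enumerate(family.markers):
            x, y = phase.x_allele[marker.id], phase.y_allele[marker.id]
            if x is None or y is None:
                labels.append(UNINFORMATIVE)
                continue
            allele = _paternal_allele(
                family.genotypes[i][j], father_g[j], mother_g[j]
            )
            if allele == x:
                labels.append("X")
            elif allele == y:
                labels.append("Y")
            else:
                labels.append(UNINFORMATIVE)
        # crossover intervals between adjacent informative markers
        xints: list[tuple[str, str]] = []
        prev_j = None
        for j, lab in enumerate(labels):
            if lab == UNINFORMATIVE:
                continue
            if prev_j is not None and labels[prev_j] != lab:
                xints.append(
                    (family.markers[prev_j].id, family.markers[j].id)
                )
            prev_j = j
        oid = family.individuals[i].id
        out[oid] = TransmittedHaplotype(oid, labels, xints)
    return out


# ---------------------------------------------------------------------------
# Recombinant screening
# ---------------------------------------------------------------------------

def find_recombinants(
    family: GenotypeMatrix,
    flank_left: str,
    flank_right: str,
    anchor_marker: str | None = None,
) -> RecombinantReport:
    """Screen offspring whose paternal type differs between the two flanking
    markers.

    Offspring uninformative at either flank are listed separately and not
    counted as recombinant or nonrecombinant.  *anchor_marker* defaults to
    the left flank.
    """
    jl = family.marker_index(flank_left)
    jr = family.marker_index(flank_right)
    phase = infer_paternal_phase(family, anchor_marker or flank_left)
    haps = transmitted_types(family, phase)
    recombinants: list[str] = []
    uninformative: list[str] = []
    for oid, th in haps.items():
        tl, tr = th.labels[jl], th.labels[jr]
        if UNINFORMATIVE in (tl, tr):
            uninformative.append(oid)
        elif tl != tr:
            recombinants.append(oid)
    sexes = {
        ind.id: ind.sex
        for ind in family.individuals
        if ind.role == "offspring"
    }
    return RecombinantReport(
        recombinant_ids=recombinants,
        haplotypes={oid: haps[oid] for oid in recombinants},
        n_screened=len(haps),
        uninformative_ids=uninformative,
        markers=list(family.markers),
        sexes=sexes,
    )


# ---------------------------------------------------------------------------
# Interval refinement
# ---------------------------------------------------------------------------

def refine_sd_interval(reports: list[RecombinantReport]) -> RefineResult:
    """Intersect recombinant haplotypes with phenotypic sex to delimit the
    candidate interval.

    A marker is *excluded* when any offspring's transmitted type there
    contradicts its sex (male = Y, female = X).  Candidate intervals are the
    maximal runs of consecutive non-excluded markers, reported as the open
    interval between the innermost excluding markers on each side (falling
    back to the outermost map positions at the edges).  More than one run is
    flagged ambiguous.
    """
    if not reports:
        raise ValueError("need at least one recombinant report")
    markers = reports[0].markers
    ids = [m.id for m in markers]
    for rep in reports[1:]:
        if [m.id for m in rep.markers] != ids:
            raise ValueError("all reports must share one marker map")
    n_rec = sum(len(r.recombinant_ids) for r in reports)
    if n_rec == 0:
        raise ValueError("no recombinants to refine with")

    mismatches = {mid: 0 for mid in ids}
    for rep in reports:
        for oid in rep.recombinant_ids:
            sex = rep.sexes.get(oid)
            if sex not in ("male", "female"):
                raise ValueError(f"recombinant {oid} has unknown sex")
            expected = "Y" if sex == "male" else "X"
            for mid, lab in zip(ids, rep.haplotypes[oid].labels):
                if lab != UNINFORMATIVE and lab != expected:
                    mismatches[mid] += 1

    excluded = [mismatches[mid] > 0 for mid in ids]
    if all(excluded):
        raise NoIntervalError(
            "every marker contradicts some recombinant's sex; check "
            "genotyping and phenotyping"
        )

    # maximal runs of consecutive non-excluded markers
    runs: list[tuple[int, int]] = []
    start = None
    for j, ex in enumerate(excluded):
        if not ex and start is None:
            start = j
        elif ex and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(ids) - 1))

    chrom = markers[0].chrom
    intervals = []
    for lo, hi in runs:
        left = markers[lo - 1] if lo > 0 else None
        right = markers[hi + 1] if hi + 1 < len(markers) else None
        start_bp = left.pos_bp if left else markers[0].pos_bp
        end_bp = right.pos_bp if right else markers[-1].pos_bp
        intervals.append(
            Interval(
                chrom,
                start_bp,
                end_bp,
                left.id if left else None,
                right.id if right else None,
            )
        )
    return RefineResult(intervals, len(intervals) > 1, mismatches)
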