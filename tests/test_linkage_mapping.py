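import numpy as np
import pytest

from protosex.data_model import GenotypeMatrix, Individual, Marker, MarkerMap
from protosex.linkage_mapping import (
    NoIntervalError,
    PhaseUndeterminedError,
    RecombinantReport,
    TransmittedHaplotype,
    find_recombinants,
    infer_paternal_phase,
    refine_sd_interval,
    transmitted_types,
)
from protosex.synthetic_data import (
    FamilySimParams,
    default_family_map,
    simulate_family,
)

UNINF = "uninformative"


def build_family(marker_labels, offspring):
    """Hand-build a family matrix.

    marker_labels: list of (marker_id, pos, father_x, father_y, mother_allele)
    offspring: list of (id, sex, list of transmitted paternal side 'X'/'Y')
    """
    markers = []
    fx, fy, mo = {}, {}, {}
    for mid, pos, x, y, m in marker_labels:
        alleles = frozenset({x, y, m})
        markers.append(Marker(mid, "c", pos, "snp", alleles))
        fx[mid], fy[mid], mo[mid] = x, y, m
    inds = [
        Individual("father", "male", "fam", "father"),
        Individual("mother", "female", "fam", "mother"),
    ]
    rows = [
        [tuple(sorted((fx[m.id], fy[m.id]))) for m in markers],
        [(mo[m.id], mo[m.id]) for m in markers],
    ]
    for oid, sex, sides in offspring:
        inds.append(Individual(oid, sex, "fam", "offspring"))
        row = []
        for m, side in zip(markers, sides):
            pat = fx[m.id] if side == "X" else fy[m.id]
            row.append(tuple(sorted((pat, mo[m.id]))))
        rows.append(row)
    return GenotypeMatrix(inds, markers, rows)


SIX_MARKERS = [
    (f"m{j + 1}", 1000 * (j + 1), "A", "C", "A") for j in range(6)
]


class TestInferPaternalPhase:
    def test_recovers_simulator_truth(self):
        mmap = default_family_map()
        matrix, truth = simulate_family(
            FamilySimParams(200, mmap, "m4", seed=1)
        )
        phase = infer_paternal_phase(matrix, "m4")
        for mid in phase.informative_markers():
            assert phase.x_allele[mid] == truth.father_x[mid]
            assert phase.y_allele[mid] == truth.father_y[mid]

    def test_father_homozygous_marker_uninformative(self):
        labels = list(SIX_MARKERS)
        labels[2] = ("m3", 3000, "A", "A", "A")  # father hom at m3
        fam = build_family(
            labels,
            [
                ("o1", "male", ["Y"] * 6),
                ("o2", "female", ["X"] * 6),
            ],
        )
        phase = infer_paternal_phase(fam, "m1")
        assert phase.x_allele["m3"] is None
        assert "m3" not in phase.informative_markers()

    def test_two_offspring_same_transmission_everywhere_errors(self):
        # both offspring received the same paternal allele at every marker
        # beyond the anchor: no marker can be phased
        fam = build_family(
            SIX_MARKERS,
            [
                ("o1", "male", ["Y", "X", "X", "X", "X", "X"]),
                ("o2", "female", ["X", "X", "X", "X", "X", "X"]),
            ],
        )
        with pytest.raises(PhaseUndeterminedError, match="beyond the anchor"):
            infer_paternal_phase(fam, "m1")

    def test_no_offspring_errors(self):
        fam = build_family(SIX_MARKERS, [("o1", "male", ["Y"] * 6)])
        fam2 = GenotypeMatrix(
            fam.individuals[:2], fam.markers, fam.genotypes[:2]
        )
        with pytest.raises(PhaseUndeterminedError, match="no offspring"):
            infer_paternal_phase(fam2, "m1")


class TestFindRecombinants:
    def test_hand_built_switch_between_m3_m4(self):
        fam = build_family(
            SIX_MARKERS,
            [
                ("nrm", "male", ["Y"] * 6),
                ("nrf", "female", ["X"] * 6),
                ("rec", "male", ["X", "X", "X", "Y", "Y", "Y"]),
            ],
        )
        report = find_recombinants(fam, "m1", "m6")
        assert report.recombinant_ids == ["rec"]
        th = report.haplotypes["rec"]
        assert th.crossover_intervals == [("m3", "m4")]

    def test_simulated_family_matches_truth(self):
        mmap = default_family_map()
        matrix, truth = simulate_family(
            FamilySimParams(400, mmap, "m4", seed=2)
        )
        report = find_recombinants(matrix, "m1", "m8", anchor_marker="m4")
        expected = {
            oid
            for oid, labels in truth.paternal_labels.items()
            if labels[0] != labels[-1]
        }
        assert set(report.recombinant_ids) == expected

    def test_zero_cm_family_empty(self):
        markers = [
            Marker(f"m{j}", "c", 1000 * (j + 1), "snp", frozenset({"A", "C"}))
            for j in range(4)
        ]
        mmap = MarkerMap(markers, [0.0] * 4, [0.0] * 4)
        matrix, _ = simulate_family(FamilySimParams(300, mmap, "m1", seed=3))
        report = find_recombinants(matrix, "m0", "m3", anchor_marker="m1")
        assert report.recombinant_ids == []

    def test_unknown_marker(self):
        fam = build_family(SIX_MARKERS, [("o1", "male", ["Y"] * 6)])
        with pytest.raises(KeyError):
            find_recombinants(fam, "m1", "nope")


# ---------------------------------------------------------------------------
# Brute-force oracle: test every candidate causal placement directly
# ---------------------------------------------------------------------------

def consistent_positions(report: RecombinantReport):
    """All causal placements (marker index or gap between adjacent markers)
    consistent with every recombinant's sex, derived from first principles.

    At a marker: the transmitted type there (if informative) must equal the
    sex-expected type.  In a gap: if the nearest informative labels on both
    sides agree, that type must match; a flanking disagreement means a
    crossover could sit there, so no constraint.
    """
    n = len(report.markers)
    ok_marker = [True] * n
    ok_gap = [True] * (n - 1)
    for oid in report.recombinant_ids:
        expected = "Y" if report.sexes[oid] == "male" else "X"
        labels = report.haplotypes[oid].labels
        for j, lab in enumerate(labels):
            if lab != UNINF and lab != expected:
                ok_marker[j] = False
        for g in range(n - 1):
            left = next(
                (labels[j] for j in range(g, -1, -1) if labels[j] != UNINF),
                None,
            )
            right = next(
                (labels[j] for j in range(g + 1, n) if labels[j] != UNINF),
                None,
            )
            if left is not None and left == right and left != expected:
                ok_gap[g] = False
    return ok_marker, ok_gap


class TestRefineInterval:
    def test_fig_style_toy_against_oracle(self):
        # recombinant male: Y at m1-m3, uninformative m4, X at m5-m6
        # recombinant female: X at m1-m4, uninformative m5, Y at m6
        markers = [Marker(f"m{j+1}", "c", 1000 * (j + 1), "snp",
                          frozenset({"A", "C"})) for j in range(6)]
        haps = {
            "rm": TransmittedHaplotype(
                "rm", ["Y", "Y", "Y", UNINF, "X", "X"], [("m3", "m5")]
            ),
            "rf": TransmittedHaplotype(
                "rf", ["X", "X", "X", "X", UNINF, "Y"], [("m4", "m6")]
            ),
        }
        report = RecombinantReport(
            ["rm", "rf"], haps, 2, [], markers,
            {"rm": "male", "rf": "female"},
        )
        result = refine_sd_interval([report])
        assert not result.ambiguous
        iv = result.interval
        # oracle: markers m1-m4 and gaps up to m5 are consistent
        ok_marker, ok_gap = consistent_positions(report)
        assert ok_marker == [True, True, True, True, False, False]
        last_ok = max(j for j, ok in enumerate(ok_marker) if ok)
        first_excl_right = last_ok + 1
        assert iv.end_bp == markers[first_excl_right].pos_bp
        assert iv.start_bp == markers[0].pos_bp  # no exclusion on the left

    def test_single_recombinant_one_constraint(self):
        markers = [Marker(f"m{j+1}", "c", 1000 * (j + 1), "snp",
                          frozenset({"A", "C"})) for j in range(6)]
        haps = {
            "r1": TransmittedHaplotype(
                "r1", ["Y", "Y", "Y", "X", "X", "X"], [("m3", "m4")]
            )
        }
        report = RecombinantReport(
            ["r1"], haps, 1, [], markers, {"r1": "male"}
        )
        result = refine_sd_interval([report])
        assert result.interval.right_flank_marker == "m4"
        assert result.interval.end_bp == 4000

    def test_every_marker_excluded_raises(self):
        markers = [Marker(f"m{j+1}", "c", 1000 * (j + 1), "snp",
                          frozenset({"A", "C"})) for j in range(2)]
        haps = {
            "r1": TransmittedHaplotype("r1", ["X", "X"], []),
        }
        report = RecombinantReport(
            ["r1"], haps, 1, [], markers, {"r1": "male"}
        )
        with pytest.raises(NoIntervalError):
            refine_sd_interval([report])

    @pytest.mark.parametrize("seed", range(12))
    def test_simulated_interval_contains_causal(self, seed):
        mmap = default_family_map()
        causal_pos = mmap.markers[mmap.marker_index("m4")].pos_bp
        matrix, _ = simulate_family(
            FamilySimParams(600, mmap, "m4", seed=seed)
        )
        report = find_recombinants(matrix, "m1", "m8", anchor_marker="m4")
        if not report.recombinant_ids:
            pytest.skip("no recombinants at this seed")
        result = refine_sd_interval([report])
        assert any(
            iv.start_bp <= causal_pos <= iv.end_bp for iv in result.intervals
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle_on_simulations(self, seed):
        mmap = default_family_map()
        matrix, _ = simulate_family(
            FamilySimParams(500, mmap, "m4", seed=100 + seed)
        )
        report = find_recombinants(matrix, "m1", "m8", anchor_marker="m4")
        if not report.recombinant_ids:
            pytest.skip("no recombinants at this seed")
        ok_marker, _ = consistent_positions(report)
        if not any(ok_marker):
            with pytest.raises(NoIntervalError):
                refine_sd_interval([report])
            return
        result = refine_sd_interval([report])
        # each returned interval covers exactly a maximal run of consistent
        # markers; every consistent marker falls inside some interval
        markers = report.markers
        covered = set()
        for iv in result.intervals:
            for j, m in enumerate(markers):
                if iv.start_bp <= m.pos_bp <= iv.end_bp and ok_marker[j]:
                    covered.add(j)
        assert covered == {j for j, ok in enumerate(ok_marker) if ok}

    def test_monotonicity_adding_recombinants_never_widens(self):
        mmap = default_family_map()
        matrix, _ = simulate_family(
            FamilySimParams(800, mmap, "m4", seed=77)
        )
        report = find_recombinants(matrix, "m1", "m8", anchor_marker="m4")
        if len(report.recombinant_ids) < 2:
            pytest.skip("need >= 2 recombinants")
        # use first k recombinants, growing k
        prev_len = None
        for k in range(1, len(report.recombinant_ids) + 1):
            sub = RecombinantReport(
                report.recombinant_ids[:k],
                {o: report.haplotypes[o] for o in report.recombinant_ids[:k]},
                report.n_screened,
                [],
                report.markers,
                report.sexes,
            )
            result = refine_sd_interval([sub])
            width = result.interval.length_bp
            if prev_len is not None:
                assert width <= prev_len
            prev_len = width
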