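"""End-to-end orchestration: simulate -> linkage -> variants -> association
-> LD -> trans-species, from one plain-text config, with a run manifest.

Identical config + seeds produce byte-identical outputs; the manifest
records a config hash and per-output checksums so that any change of input
or parameter is detectable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .data_model import write_genotype_table, write_marker_map, write_vcf
from .synthetic_data import (
    ClonePairParams,
    FamilySimParams,
    WildSimParams,
    default_family_map,
    simulate_clone_pair,
    simulate_family,
    simulate_species_panels,
    simulate_wild_population,
)
from . import association as assoc_mod
from . import linkage_disequilibrium as ld_mod
from . import linkage_mapping as lm
from . import trans_species as ts
from . import variant_screening as vs

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "linkage": True,
        "variants": True,
        "association": True,
        "ld": True,
        "trans_species": True,
    },
    "wild": {},  # WildSimParams overrides
    "family": {"n_offspring": 300, "informative_fraction": 1.0},
    "clones": {"length_bp": 14_000, "target_identity": 0.994, "n_males": 9},
    "species": {"n_species": 3, "sizes": [[8, 8], [8, 8], [6, 7]], "shared_snp": True},
    "association": {
        "model": "recessive",
        "maf_min": 0.1,
        "call_rate_min": 0.99,
        "permutations": 0,
    },
}


@dataclass
class PipelineConfig:
    raw: dict[str, Any]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, val in d.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        return cls(merged)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    def stage(self, name: str) -> bool:
        return bool(self.raw["stages"].get(name, False))

    def hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {
                name: {
                    "path": str(p),
                    "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                }
                for name, p in outputs.items()
            },
            "wall_clock_s": round(seconds, 3),
        }

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(
            json.dumps(
                {
                    "tool_version": self.tool_version,
                    "config_hash": self.config_hash,
                    "stages": self.stages,
                },
                indent=2,
                sort_keys=True,
            )
        )
        tmp.replace(path)  # atomic on POSIX


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with path.open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _assoc_tsv(path: Path, results: list[assoc_mod.AssocResult]) -> None:
    with path.open("w") as fh:
        fh.write(
            "#marker_id\tmaf\tcall_rate\tmodel\tp_one_sided\tp_two_sided"
            "\tp_bonferroni\tp_permutation\tfiltered\tfilter_reason\n"
        )
        for r in results:
            def fmt(x):
                return "NA" if x is None else f"{x:.6g}"
            fh.write(
                "\t".join(
                    [
                        r.marker_id,
                        f"{r.maf:.6g}",
                        f"{r.call_rate:.6g}",
                        r.model,
                        fmt(r.p_one_sided),
                        fmt(r.p_two_sided),
                        fmt(r.p_bonferroni),
                        fmt(r.p_permutation),
                        str(int(r.filtered)),
                        r.filter_reason or "NA",
                    ]
                )
                + "\n"
            )


def _ld_tsv(path: Path, pairs: list[ld_mod.LDPair]) -> None:
    with path.open("w") as fh:
        fh.write("#marker_i\tmarker_j\tdistance_bp\tD\tDprime\tr2\tLOD\tn_used\n")
        for p in pairs:
            fh.write(
                f"{p.marker_i}\t{p.marker_j}\t{p.distance_bp}\t"
                f"{p.D:.6g}\t{p.Dprime:.6g}\t{p.r2:.6g}\t{p.LOD:.6g}\t"
                f"{p.n_used}\n"
            )


def _recombinant_tsv(path: Path, report: lm.RecombinantReport) -> None:
    """One row per recombinant, one column per marker: X/Y/. box diagram."""
    with path.open("w") as fh:
        fh.write(
            "#offspring_id\tsex\t"
            + "\t".join(m.id for m in report.markers)
            + "\n"
        )
        for oid in report.recombinant_ids:
            th = report.haplotypes[oid]
            cells = [
                lab if lab in ("X", "Y") else "." for lab in th.labels
            ]
            fh.write(f"{oid}\t{report.sexes[oid]}\t" + "\t".join(cells) + "\n")


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path) -> RunManifest:
    """Execute the enabled stages in dependency order, writing all outputs
    under *out_dir* and a ``manifest.json`` at the end."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, config.hash())
    seed = int(config["seed"])
    ss = np.random.SeedSequence(seed)
    sub_seeds = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ["wild", "family", "clones", "species"], ss.spawn(4)
        )
    }

    wild_matrix = None
    family_matrix = None
    family_map = None
    species_panels = None
    clone_data = None

    if config.stage("simulate"):
        t0 = time.perf_counter()
        outputs: dict[str, Path] = {}

        wild_params = WildSimParams(**config["wild"], seed=sub_seeds["wild"])
        wild_matrix, _ = simulate_wild_population(wild_params)
        p = out / "wild_genotypes.tsv"
        write_genotype_table(wild_matrix, p)
        outputs["wild_genotypes"] = p

        fam_cfg = dict(config["family"])
        family_map = default_family_map()
        fam_params = FamilySimParams(
            n_offspring=int(fam_cfg.get("n_offspring", 300)),
            map=family_map,
            causal_marker=fam_cfg.get(
                "causal_marker", family_map.markers[len(family_map.markers) // 2].id
            ),
            informative_fraction=float(fam_cfg.get("informative_fraction", 1.0)),
            seed=sub_seeds["family"],
        )
        family_matrix, _ = simulate_family(fam_params)
        p = out / "family_genotypes.tsv"
        write_genotype_table(family_matrix, p)
        outputs["family_genotypes"] = p
        p = out / "family_map.tsv"
        write_marker_map(family_map, p)
        outputs["family_map"] = p

        clone_cfg = dict(config["clones"])
        n_clone_males = int(clone_cfg.pop("n_males", 9))
        clone_params = ClonePairParams(
            length_bp=int(clone_cfg.get("length_bp", 14_000)),
            target_identity=float(clone_cfg.get("target_identity", 0.994)),
            seed=sub_seeds["clones"],
        )
        x_seq, y_seq = simulate_clone_pair(clone_params)
        rng = np.random.default_rng(sub_seeds["clones"] + 1)
        diff_sites = [i for i, (a, b) in enumerate(zip(x_seq, y_seq)) if a != b]
        causal_site = diff_sites[len(diff_sites) // 2] if diff_sites else None
        pairs: dict[str, tuple[str, str]] = {}
        for k in range(n_clone_males):
            y = list(x_seq)
            for site in diff_sites:
                if site == causal_site or rng.random() < 0.5:
                    y[site] = y_seq[site]
            pairs[f"male{k + 1}"] = (x_seq, "".join(y))
        clone_data = (x_seq, pairs, causal_site)
        p = out / "clones.fasta"
        recs = {"ref_X": x_seq}
        for male, (mx, my) in pairs.items():
            recs[f"{male}_X"] = mx
            recs[f"{male}_Y"] = my
        _write_fasta(p, recs)
        outputs["clones"] = p

        sp_cfg = dict(config["species"])
        species_panels = simulate_species_panels(
            n_species=int(sp_cfg.get("n_species", 3)),
            sizes=[tuple(x) for x in sp_cfg.get("sizes", [[8, 8], [8, 8], [6, 7]])],
            shared_snp=bool(sp_cfg.get("shared_snp", True)),
            seed=sub_seeds["species"],
        )
        for name, matrix in species_panels:
            p = out / f"panel_{name}.tsv"
            write_genotype_table(matrix, p)
            outputs[f"panel_{name}"] = p

        manifest.record("simulate", outputs, time.perf_counter() - t0)

    if config.stage("linkage"):
        if family_matrix is None:
            raise RuntimeError("linkage stage requires the simulate stage")
        t0 = time.perf_counter()
        flank_l = family_map.markers[0].id
        flank_r = family_map.markers[-1].id
        fam_cfg = dict(config["family"])
        anchor = fam_cfg.get(
            "causal_marker", family_map.markers[len(family_map.markers) // 2].id
        )
        report = lm.find_recombinants(
            family_matrix, flank_l, flank_r, anchor_marker=anchor
        )
        p_tsv = out / "recombinants.tsv"
        _recombinant_tsv(p_tsv, report)
        outputs = {"recombinants": p_tsv}
        if report.recombinant_ids:
            refined = lm.refine_sd_interval([report])
            iv = refined.interval
            p_json = out / "sd_interval.json"
            p_json.write_text(
                json.dumps(
                    {
                        "chrom": iv.chrom,
                        "start_bp": iv.start_bp,
                        "end_bp": iv.end_bp,
                        "length_bp": iv.length_bp,
                        "left_flank_marker": iv.left_flank_marker,
                        "right_flank_marker": iv.right_flank_marker,
                        "ambiguous": refined.ambiguous,
                        "n_candidate_intervals": len(refined.intervals),
                    },
                    indent=2,
                )
            )
            outputs["sd_interval"] = p_json
        manifest.record("linkage", outputs, time.perf_counter() - t0)

    if config.stage("variants"):
        if clone_data is None:
            raise RuntimeError("variants stage requires the simulate stage")
        t0 = time.perf_counter()
        x_seq, pairs, _ = clone_data
        identity = min(
            vs.sequence_identity(mx, my) for mx, my in pairs.values()
        )
        calls = vs.call_variants(pairs, x_seq, chrom="cloneref")
        sexes = {male: "male" for male in pairs}
        candidates, counts = vs.screen_xy_pattern(calls, sexes)
        p = out / "variant_screen.tsv"
        with p.open("w") as fh:
            fh.write("# indel screening: not implemented (substitutions only)\n")
            fh.write(f"# min X/Y clone identity: {identity:.4f}\n")
            fh.write("#pos_bp\tref\talt\tn_het_males\tn_males\txy_pattern\n")
            cand_pos = {c.pos_bp for c in candidates}
            for call in calls:
                n_het, n_m = counts[call.pos_bp]
                fh.write(
                    f"{call.pos_bp}\t{call.ref_allele}\t"
                    f"{','.join(call.alt_alleles)}\t{n_het}\t{n_m}\t"
                    f"{int(call.pos_bp in cand_pos)}\n"
                )
        manifest.record("variants", {"variant_screen": p}, time.perf_counter() - t0)

    if config.stage("association"):
        if wild_matrix is None:
            raise RuntimeError("association stage requires the simulate stage")
        t0 = time.perf_counter()
        a_cfg = config["association"]
        results = assoc_mod.associate(
            wild_matrix,
            model=a_cfg.get("model", "recessive"),
            maf_min=float(a_cfg.get("maf_min", 0.1)),
            call_rate_min=float(a_cfg.get("call_rate_min", 0.99)),
            n_perm=int(a_cfg.get("permutations", 0)),
            seed=seed,
        )
        p = out / "association.tsv"
        _assoc_tsv(p, results)
        outputs = {"association": p}
        # -log10(p) track for plotting layers
        p_track = out / "association_track.tsv"
        pos = {m.id: m.pos_bp for m in wild_matrix.markers}
        with p_track.open("w") as fh:
            fh.write("#marker_id\tpos_bp\tminus_log10_p\n")
            for r in results:
                if r.p_two_sided is not None:
                    fh.write(
                        f"{r.marker_id}\t{pos[r.marker_id]}\t"
                        f"{-np.log10(r.p_two_sided):.4f}\n"
                    )
        outputs["association_track"] = p_track
        manifest.record("association", outputs, time.perf_counter() - t0)

    if config.stage("ld"):
        if wild_matrix is None:
            raise RuntimeError("ld stage requires the simulate stage")
        t0 = time.perf_counter()
        a_cfg = config["association"]
        filters = assoc_mod.apply_marker_filters(
            wild_matrix,
            float(a_cfg.get("maf_min", 0.1)),
            float(a_cfg.get("call_rate_min", 0.99)),
        )
        passing = [m.id for m in wild_matrix.markers if filters[m.id].passed]
        pairs_ld = ld_mod.ld_matrix(wild_matrix, passing)
        p = out / "ld_pairs.tsv"
        _ld_tsv(p, pairs_ld)
        manifest.record("ld", {"ld_pairs": p}, time.perf_counter() - t0)

    if config.stage("trans_species"):
        if species_panels is None:
            raise RuntimeError("trans_species stage requires the simulate stage")
        t0 = time.perf_counter()
        panels = [
            ts.SpeciesPanel(name, matrix) for name, matrix in species_panels
        ]
        report = ts.conservation_report(panels)
        p = out / "conservation.tsv"
        with p.open("w") as fh:
            fh.write(
                "#chrom\tpos_bp\talleles\tpresent_in\tassociated_in\t"
                "pooled_p\tverdict\n"
            )
            for v in report.variants:
                fh.write(
                    f"{v.chrom}\t{v.pos_bp}\t{'/'.join(sorted(v.alleles))}\t"
                    f"{','.join(v.present_in)}\t"
                    f"{','.join(v.associated_in) or 'NA'}\t"
                    f"{v.pooled_p:.6g}\t{v.verdict}\n"
                )
        manifest.record(
            "trans_species", {"conservation": p}, time.perf_counter() - t0
        )

    manifest.write(out / "manifest.json")
    return manifest
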