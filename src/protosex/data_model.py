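"""Core domain types and text-format I/O for the locus-discovery pipeline.

Conventions used throughout the package:

* Coordinates are 1-based offsets from the 5' end of the named reference
  clone; intervals are closed, so ``length_bp = end_bp - start_bp + 1``.
* Genotypes are *unordered* allele pairs, stored lexicographically sorted.
  Phase is never stored in a :class:`GenotypeMatrix`.
* The missing-genotype sentinel in text files is ``./.``; missing sex is
  ``U`` and such individuals are excluded from every sex-conditioned
  computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "Marker",
    "Individual",
    "GenotypeMatrix",
    "MarkerMap",
    "Interval",
    "Genotype",
    "MISSING",
    "ParseError",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_map",
    "write_marker_map",
    "write_vcf",
    "summarize_counts",
]

#: an unordered allele pair, stored sorted; ``None`` means missing
Genotype = Optional[tuple[str, str]]

MISSING: Genotype = None

_SEX_CODES = {"F": "female", "M": "male", "U": "unknown"}
_SEX_LETTERS = {v: k for k, v in _SEX_CODES.items()}
_ROLES = {"father", "mother", "offspring", "unrelated"}
_KINDS = {"snp", "microsatellite"}


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Marker:
    """A genetic marker on a named reference clone/scaffold."""

    id: str
    chrom: str
    pos_bp: int
    kind: str = "snp"
    alleles: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1")
        if self.kind not in _KINDS:
            raise ValueError(f"marker {self.id}: unknown kind {self.kind!r}")
        if not self.alleles:
            raise ValueError(f"marker {self.id}: alleles must be non-empty")
        if self.kind == "snp" and any(len(a) != 1 for a in self.alleles):
            raise ValueError(f"marker {self.id}: snp alleles must be single bases")
        object.__setattr__(self, "alleles", frozenset(self.alleles))

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2


@dataclass(frozen=True)
class Individual:
    """A sampled fish with phenotypic sex and pedigree role."""

    id: str
    sex: str = "unknown"
    population: str = "wild"
    role: str = "unrelated"

    def __post_init__(self) -> None:
        if self.sex not in _SEX_CODES.values():
            raise ValueError(f"individual {self.id}: bad sex {self.sex!r}")
        if self.role not in _ROLES:
            raise ValueError(f"individual {self.id}: bad role {self.role!r}")


class GenotypeMatrix:
    """Individuals x markers of unordered allele pairs, with explicit missing.

    Parameters
    ----------
    individuals
        Ordered individuals; ids must be unique.
    markers
        Ordered markers.
    genotypes
        ``genotypes[i][j]`` is the sorted allele pair of individual *i* at
        marker *j*, or ``None`` when missing.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        markers: Sequence[Marker],
        genotypes: Sequence[Sequence[Genotype]],
    ):
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual id(s): {dup}")
        if len(genotypes) != len(individuals):
            raise ValueError("genotype rows do not match number of individuals")
        norm: list[list[Genotype]] = []
        for i, row in enumerate(genotypes):
            if len(row) != len(markers):
                raise ValueError(
                    f"individual {ids[i]}: {len(row)} genotypes for "
                    f"{len(markers)} markers"
                )
            out_row: list[Genotype] = []
            for j, g in enumerate(row):
                if g is None:
                    out_row.append(None)
                    continue
                a, b = sorted(g)
                bad = {a, b} - set(markers[j].alleles)
                if bad:
                    raise ValueError(
                        f"individual {ids[i]}, marker {markers[j].id}: "
                        f"allele(s) {sorted(bad)} not in marker alleles"
                    )
                out_row.append((a, b))
            norm.append(out_row)
        self.individuals = list(individuals)
        self.markers = list(markers)
        self.genotypes = norm
        self._ind_index = {ind.id: i for i, ind in enumerate(self.individuals)}
        self._marker_index = {m.id: j for j, m in enumerate(self.markers)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker_id!r}") from None

    def individual_index(self, individual_id: str) -> int:
        try:
            return self._ind_index[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual id: {individual_id!r}") from None

    def genotype(self, individual_id: str, marker_id: str) -> Genotype:
        return self.genotypes[self.individual_index(individual_id)][
            self.marker_index(marker_id)
        ]

    def column(self, marker_id: str) -> list[Genotype]:
        j = self.marker_index(marker_id)
        return [row[j] for row in self.genotypes]

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.individual_index(i) for i in ids]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            self.markers,
            [self.genotypes[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.markers == other.markers
            and self.genotypes == other.genotypes
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeMatrix {self.n_individuals} individuals x "
            f"{self.n_markers} markers>"
        )


@dataclass
class MarkerMap:
    """Markers ordered by physical position with cumulative sex-specific cM.

    ``cm_male`` totals are typically smaller than ``cm_female`` when male
    recombination is reduced.
    """

    markers: list[Marker]
    cm_female: list[float]
    cm_male: list[float]

    def __post_init__(self) -> None:
        n = len(self.markers)
        if len(self.cm_female) != n or len(self.cm_male) != n:
            raise ValueError("cM vectors must match number of markers")
        pos = [m.pos_bp for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker pos_bp must be strictly increasing")
        for name, cm in (("cm_female", self.cm_female), ("cm_male", self.cm_male)):
            if any(b < a for a, b in zip(cm, cm[1:])):
                raise ValueError(f"{name} must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        for j, m in enumerate(self.markers):
            if m.id == marker_id:
                return j
        raise KeyError(f"unknown marker id: {marker_id!r}")


@dataclass(frozen=True)
class Interval:
    """A closed 1-based interval on a reference clone, with flanking markers."""

    chrom: str
    start_bp: int
    end_bp: int
    left_flank_marker: str | None = None
    right_flank_marker: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, pos_bp: int) -> bool:
        return self.start_bp <= pos_bp <= self.end_bp


# ---------------------------------------------------------------------------
# Genotype table TSV
# ---------------------------------------------------------------------------

def _format_genotype(g: Genotype) -> str:
    return "./." if g is None else f"{g[0]}/{g[1]}"


def _parse_genotype(cell: str, marker: Marker, line: int) -> Genotype:
    if cell == "./.":
        return None
    parts = cell.split("/")
    if len(parts) != 2 or not all(parts):
        raise ParseError(f"malformed genotype cell {cell!r}", line)
    bad = set(parts) - set(marker.alleles)
    if bad:
        raise ParseError(
            f"allele(s) {sorted(bad)} inconsistent with marker "
            f"{marker.id} (alleles {sorted(marker.alleles)})",
            line,
        )
    a, b = sorted(parts)
    return (a, b)


def read_genotype_table(
    path: Union[str, Path], markers: Sequence[Marker] | None = None
) -> GenotypeMatrix:
    """Read a genotype TSV into a :class:`GenotypeMatrix`.

    The dialect is a header line
    ``#individual_id<TAB>sex<TAB>population<TAB>role<TAB><marker_id>...``
    followed by one row per individual; sex is F/M/U and genotype cells are
    ``A/B`` or ``./.``.  When *markers* is omitted, marker definitions come
    from optional ``##marker=`` metadata lines (id, chrom, pos_bp, kind,
    comma-separated alleles); without those, alleles are inferred from the
    observed cells and ordinal positions are used.
    """
    path = Path(path)
    all_lines = path.read_text().splitlines()
    if not all_lines:
        raise ParseError("empty file", 1)
    # optional ##marker= metadata lines carry chrom/pos/kind/alleles
    meta: dict[str, Marker] = {}
    data: list[tuple[int, str]] = []
    for ln, raw in enumerate(all_lines, start=1):
        if raw.startswith("##marker="):
            fields = raw[len("##marker=") :].split("\t")
            if len(fields) != 5:
                raise ParseError("malformed ##marker= metadata", ln)
            mid, chrom, pos, kind, alleles = fields
            meta[mid] = Marker(
                mid, chrom, int(pos), kind, frozenset(alleles.split(","))
            )
        elif not raw.startswith("##"):
            data.append((ln, raw))
    if not data:
        raise ParseError("missing '#'-prefixed header line", 1)
    header = data[0][1]
    if not header.startswith("#"):
        raise ParseError("missing '#'-prefixed header line", data[0][0])
    cols = header.lstrip("#").split("\t")
    if cols[:4] != ["individual_id", "sex", "population", "role"]:
        raise ParseError(
            "header must start with individual_id, sex, population, role", 1
        )
    marker_ids = cols[4:]

    rows: list[tuple[int, Individual, list[str]]] = []
    seen_ids: set[str] = set()
    for ln, raw in data[1:]:
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 4 + len(marker_ids):
            raise ParseError(
                f"expected {4 + len(marker_ids)} columns, got {len(fields)}", ln
            )
        iid, sex_code, pop, role = fields[:4]
        if iid in seen_ids:
            raise ParseError(f"duplicate individual id {iid!r}", ln)
        seen_ids.add(iid)
        if sex_code not in _SEX_CODES:
            raise ParseError(f"bad sex code {sex_code!r} (expected F/M/U)", ln)
        if role not in _ROLES:
            raise ParseError(f"bad role {role!r}", ln)
        rows.append(
            (ln, Individual(iid, _SEX_CODES[sex_code], pop, role), fields[4:])
        )

    if markers is None and set(marker_ids) <= set(meta):
        markers = [meta[mid] for mid in marker_ids]
    if markers is None:
        # infer alleles per marker from the observed cells
        allele_sets: list[set[str]] = [set() for _ in marker_ids]
        for _, _, cells in rows:
            for j, cell in enumerate(cells):
                if cell != "./.":
                    allele_sets[j].update(cell.split("/"))
        markers = [
            Marker(
                mid,
                chrom="unknown",
                pos_bp=j + 1,
                kind="snp"
                if all(len(a) == 1 for a in alleles) and alleles
                else "microsatellite",
                alleles=frozenset(alleles) if alleles else frozenset({"N"}),
            )
            for j, (mid, alleles) in enumerate(zip(marker_ids, allele_sets))
        ]
    else:
        markers = list(markers)
        got = [m.id for m in markers]
        if got != marker_ids:
            raise ParseError(
                f"marker columns {marker_ids} do not match map {got}", 1
            )

    individuals = [ind for _, ind, _ in rows]
    genotypes: list[list[Genotype]] = [
        [_parse_genotype(cell, markers[j], ln) for j, cell in enumerate(cells)]
        for ln, _, cells in rows
    ]
    return GenotypeMatrix(individuals, markers, genotypes)


def write_genotype_table(matrix: GenotypeMatrix, path: Union[str, Path]) -> None:
    """Write *matrix* in the genotype TSV dialect read by
    :func:`read_genotype_table`."""
    path = Path(path)
    with path.open("w") as fh:
        for m in matrix.markers:
            fh.write(
                f"##marker={m.id}\t{m.chrom}\t{m.pos_bp}\t{m.kind}\t"
                f"{','.join(sorted(m.alleles))}\n"
            )
        header = ["individual_id", "sex", "population", "role"] + [
            m.id for m in matrix.markers
        ]
        fh.write("#" + "\t".join(header) + "\n")
        for ind, row in zip(matrix.individuals, matrix.genotypes):
            cells = [
                ind.id,
                _SEX_LETTERS[ind.sex],
                ind.population,
                ind.role,
            ] + [_format_genotype(g) for g in row]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Marker map TSV
# ---------------------------------------------------------------------------

def read_marker_map(path: Union[str, Path]) -> MarkerMap:
    """Read a marker map TSV:
    ``marker_id  chrom  pos_bp  kind  alleles  cM_female  cM_male``
    (alleles comma-separated)."""
    path = Path(path)
    markers: list[Marker] = []
    cmf: list[float] = []
    cmm: list[float] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 7:
            raise ParseError(f"expected 7 columns, got {len(fields)}", ln)
        mid, chrom, pos, kind, alleles, f_cm, m_cm = fields
        try:
            markers.append(
                Marker(mid, chrom, int(pos), kind, frozenset(alleles.split(",")))
            )
            cmf.append(float(f_cm))
            cmm.append(float(m_cm))
        except ValueError as exc:
            raise ParseError(str(exc), ln) from exc
    return MarkerMap(markers, cmf, cmm)


def write_marker_map(mmap: MarkerMap, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "#marker_id\tchrom\tpos_bp\tkind\talleles\tcM_female\tcM_male\n"
        )
        for m, f_cm, m_cm in zip(mmap.markers, mmap.cm_female, mmap.cm_male):
            fh.write(
                "\t".join(
                    [
                        m.id,
                        m.chrom,
                        str(m.pos_bp),
                        m.kind,
                        ",".join(sorted(m.alleles)),
                        f"{f_cm:.6g}",
                        f"{m_cm:.6g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(
    matrix: GenotypeMatrix,
    ref_alleles: dict[str, str],
    path: Union[str, Path],
) -> None:
    """Export SNP genotypes as an unphased VCF v4.2.

    *ref_alleles* maps marker id to its REF allele; the remaining allele(s)
    become ALT.  Microsatellite markers are rejected.
    """
    for m in matrix.markers:
        if m.kind != "snp":
            raise ValueError(
                f"unsupported marker {m.id}: VCF export is SNP-only"
            )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=protosex\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        cols += [ind.id for ind in matrix.individuals]
        fh.write("\t".join(cols) + "\n")
        for j, m in enumerate(matrix.markers):
            try:
                ref = ref_alleles[m.id]
            except KeyError:
                raise ValueError(f"no ref allele given for marker {m.id}") from None
            if ref not in m.alleles:
                raise ValueError(
                    f"ref allele {ref!r} not among alleles of marker {m.id}"
                )
            alts = sorted(set(m.alleles) - {ref})
            code = {ref: 0}
            code.update({a: i + 1 for i, a in enumerate(alts)})
            row = [
                m.chrom,
                str(m.pos_bp),
                m.id,
                ref,
                ",".join(alts) if alts else ".",
                ".",
                "PASS",
                "GT",
            ]
            for irow in matrix.genotypes:
                g = irow[j]
                if g is None:
                    row.append("./.")
                else:
                    i0, i1 = sorted((code[g[0]], code[g[1]]))
                    row.append(f"{i0}/{i1}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Genotype-count summaries
# ---------------------------------------------------------------------------

def summarize_counts(matrix: GenotypeMatrix, marker_id: str) -> dict[str, dict[str, int]]:
    """Count genotype classes per sex at one marker.

    Returns ``{"female": {...}, "male": {...}, "unknown": {...}}`` where each
    inner dict maps a genotype string like ``"CG"`` (sorted alleles, no
    separator) to its count, plus a ``"missing"`` entry.  Totals over all
    sexes equal the number of individuals.
    """
    j = matrix.marker_index(marker_id)
    out: dict[str, dict[str, int]] = {
        "female": {"missing": 0},
        "male": {"missing": 0},
        "unknown": {"missing": 0},
    }
    for ind, row in zip(matrix.individuals, matrix.genotypes):
        g = row[j]
        bucket = out[ind.sex]
        if g is None:
            bucket["missing"] += 1
        else:
            key = g[0] + g[1]
            bucket[key] = bucket.get(key, 0) + 1
    return out
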