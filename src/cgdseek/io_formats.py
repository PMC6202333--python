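"""Readers and writers for the file formats the pipeline consumes.

Conventions fixed here, once, for the whole package:

* Coordinates are 1-based inclusive (VCF convention); no 0-based view is
  exposed anywhere.
* Diploid genotypes are stored as minor-ignorant *alternate allele counts*
  0/1/2, with ``None`` for missing.  Males on the X chromosome (outside the
  pseudo-autosomal regions, which are not modelled) are hemizygous and carry
  counts 0/1 only.
* Functional consequence is consumed from a single configurable VCF INFO key
  (default ``CSQ_TERM``); the gene symbol from a second key (default
  ``GENE``).  Annotation itself (VEP-style) is upstream of this package.
* Multi-allelic sites are decomposed into one biallelic record per alternate
  allele by default; with ``decompose=False`` they raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("cgdseek")

#: Default INFO key carrying the consequence term.
CONSEQUENCE_INFO_KEY = "CSQ_TERM"
#: Default INFO key carrying the gene symbol.
GENE_INFO_KEY = "GENE"
#: Default label of the X chromosome.
X_CHROM_LABEL = "chrX"

#: Controlled vocabulary of consequence terms the package understands
#: (Sequence Ontology style).  Unlisted terms are read as "unknown".
CONSEQUENCE_VOCABULARY = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "transcript_ablation",
        "missense_variant",
        "splice_region_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
        "synonymous_variant",
        "stop_retained_variant",
        "start_retained_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "regulatory_region_variant",
        "TF_binding_site_variant",
        "intron_variant",
        "intergenic_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "non_coding_transcript_exon_variant",
        "unknown",
    }
)


class VCFParseError(ValueError):
    """Malformed VCF content; carries a 1-based line number when known."""


class UnsupportedSiteError(ValueError):
    """Multi-allelic site encountered with decomposition disabled."""


class PedigreeValidationError(ValueError):
    """Structural problem in a pedigree (cycle, sex/role conflict...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site with its functional annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "unknown"
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCE_VOCABULARY:
            object.__setattr__(self, "consequence", "unknown")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """Alternate-allele count of one individual at one variant."""

    individual_id: str
    variant: VariantRecord
    allele_count: int | None  # 0/1/2, None = missing

    def __post_init__(self) -> None:
        if self.allele_count is not None and self.allele_count not in (0, 1, 2):
            raise ValueError(f"allele_count must be 0/1/2/None, got {self.allele_count}")


@dataclass
class Individual:
    """One pedigree member."""

    id: str
    sex: str = "unknown"  # male / female / unknown
    father_id: str | None = None
    mother_id: str | None = None
    affected: str = "unknown"  # yes / no / unknown
    genotyped: bool = False
    birth_year: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated genealogy: acyclic parent graph keyed by individual id."""

    def __init__(self, individuals: Iterable[Individual] = ()):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            self.add(ind)
        self.validate()

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise PedigreeValidationError(f"duplicate individual id {ind.id!r}")
        self.individuals[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def __iter__(self):
        return iter(self.individuals.values())

    @property
    def affected_ids(self) -> list[str]:
        return [i.id for i in self if i.affected == "yes"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [i.id for i in self if i.affected == "no"]

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self if iid in (i.father_id, i.mother_id)]

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self.individuals:
                    g.add_edge(pid, ind.id)
        return g

    def topological_order(self) -> list[str]:
        """Ids ordered founders-first (every parent before its children)."""
        return list(nx.topological_sort(self.parent_graph()))

    def validate(self) -> None:
        for ind in self:
            if ind.father_id is not None and ind.father_id in self.individuals:
                f = self.individuals[ind.father_id]
                if f.sex == "female":
                    raise PedigreeValidationError(
                        f"father {f.id!r} of {ind.id!r} is recorded as female"
                    )
            if ind.mother_id is not None and ind.mother_id in self.individuals:
                m = self.individuals[ind.mother_id]
                if m.sex == "male":
                    raise PedigreeValidationError(
                        f"mother {m.id!r} of {ind.id!r} is recorded as male"
                    )
        g = self.parent_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeValidationError(f"pedigree contains a cycle: {cycle}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _find_malformed_line(path: str | Path) -> int | None:
    """Best-effort scan for the first structurally broken data line."""
    n_fixed = 8  # CHROM POS ID REF ALT QUAL FILTER INFO
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < n_fixed:
                return lineno
            try:
                int(fields[1])
            except ValueError:
                return lineno
    return None


def read_vcf_genotypes(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    consequence_key: str = CONSEQUENCE_INFO_KEY,
    gene_key: str = GENE_INFO_KEY,
    decompose: bool = True,
) -> list[tuple[VariantRecord, dict[str, int | None]]]:
    """Read a VCF into ``(VariantRecord, {sample: allele_count})`` pairs.

    Multi-allelic sites are decomposed into one record per alternate allele
    (``decompose=False`` raises :class:`UnsupportedSiteError` instead).
    Missing genotypes (``./.``) map to ``None``; haploid calls (male X) map
    to counts 0/1.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFParseError(f"{path}: cannot open as VCF: {exc}") from exc

    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise VCFParseError(f"{path}: samples not in VCF: {sorted(missing)}")
        keep_idx = [samples.index(s) for s in sample_subset]
        keep_names = list(sample_subset)
    else:
        keep_idx = list(range(len(samples)))
        keep_names = samples

    out: list[tuple[VariantRecord, dict[str, int | None]]] = []
    try:
        for var in vcf:
            alts = var.ALT
            if len(alts) > 1 and not decompose:
                raise UnsupportedSiteError(
                    f"{var.CHROM}:{var.POS} is multi-allelic and decomposition is disabled"
                )
            consequence = var.INFO.get(consequence_key) or "unknown"
            gene = var.INFO.get(gene_key) or ""
            genos = var.genotypes  # [a1, a2, phased] or [a1, phased] per sample
            for alt_index, alt in enumerate(alts, start=1):
                rec = VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    gene=str(gene),
                    consequence=str(consequence),
                )
                counts: dict[str, int | None] = {}
                for name, si in zip(keep_names, keep_idx):
                    alleles = genos[si][:-1]  # last element is the phased flag
                    alleles = [a for a in alleles if a != -2]  # ploidy padding
                    if any(a < 0 for a in alleles) or not alleles:
                        counts[name] = None
                    else:
                        counts[name] = sum(1 for a in alleles if a == alt_index)
                out.append((rec, counts))
    except (UnsupportedSiteError, VCFParseError):
        raise
    except Exception as exc:
        lineno = _find_malformed_line(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise VCFParseError(f"{path}: malformed VCF record{where}: {exc}") from exc
    return out


def write_vcf(
    variants: Sequence[tuple[VariantRecord, Mapping[str, int | None]]],
    sample_ids: Sequence[str],
    path: str | Path,
    sexes: Mapping[str, str] | None = None,
    x_label: str = X_CHROM_LABEL,
    consequence_key: str = CONSEQUENCE_INFO_KEY,
    gene_key: str = GENE_INFO_KEY,
) -> None:
    """Write biallelic records to a plain-text VCF v4.2.

    Males on the X chromosome are written as haploid genotypes.
    """
    sexes = sexes or {}
    contigs = sorted({rec.chrom for rec, _ in variants})
    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID={c}>" for c in contigs),
        f'##INFO=<ID={consequence_key},Number=1,Type=String,Description="Consequence term">',
        f'##INFO=<ID={gene_key},Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    def sort_key(item):
        rec = item[0]
        return (rec.chrom, rec.pos, rec.ref, rec.alt)

    for rec, counts in sorted(variants, key=sort_key):
        info_parts = []
        if rec.consequence and rec.consequence != "unknown":
            info_parts.append(f"{consequence_key}={rec.consequence}")
        if rec.gene:
            info_parts.append(f"{gene_key}={rec.gene}")
        info = ";".join(info_parts) or "."
        gts = []
        haploid_site = rec.chrom == x_label
        for sid in sample_ids:
            c = counts.get(sid)
            male = sexes.get(sid) == "male"
            if c is None:
                gts.append("." if (haploid_site and male) else "./.")
            elif haploid_site and male:
                if c > 1:
                    raise ValueError(f"male {sid} with allele count {c} on {x_label}")
                gts.append(str(c))
            else:
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[c])
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "male", "2": "female", "0": "unknown"}
_PED_PHENO = {"2": "yes", "1": "no", "0": "unknown", "-9": "unknown"}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file into a :class:`Pedigree`.

    Columns: family, id, father, mother, sex (1=male, 2=female, 0=unknown),
    phenotype (2=affected, 1=unaffected, 0/-9=unknown).  ``0`` as a parent id
    means founder.
    """
    path = Path(path)
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeValidationError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            _fam, iid, fid, mid, sex, pheno = fields[:6]
            individuals.append(
                Individual(
                    id=iid,
                    sex=_PED_SEX.get(sex, "unknown"),
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    affected=_PED_PHENO.get(pheno, "unknown"),
                )
            )
    if not individuals:
        logger.warning("pedigree file %s is empty", path)
    return Pedigree(individuals)


def write_pedigree(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    """Write a :class:`Pedigree` as a 6-column PED file (tab-delimited)."""
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"yes": "2", "no": "1", "unknown": "0"}
    rows = []
    for ind in pedigree:
        rows.append(
            "\t".join(
                [
                    family_id,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    sex_code[ind.sex],
                    pheno_code[ind.affected],
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs / outputs
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "gene",
    "variants",
    "model",
    "maf_internal",
    "maf_external",
    "carriers",
    "phase",
]


def write_candidates(candidates, path: str | Path) -> None:
    """Write prioritized candidates to a deterministic, sorted TSV.

    Sorted by (chrom, pos of first variant, model); byte-identical output for
    identical input.
    """
    rows = []
    for c in candidates:
        first = c.variants[0]
        maf_int = ";".join(
            "" if f.maf_internal is None else f"{f.maf_internal:.6g}" for f in c.maf_summary
        )
        maf_ext = ";".join(
            "" if f.maf_external is None else f"{f.maf_external:.6g}" for f in c.maf_summary
        )
        rows.append(
            {
                "_sort": (first.chrom, first.pos, c.model),
                "gene": first.gene,
                "variants": ";".join(str(v) for v in c.variants),
                "model": c.model,
                "maf_internal": maf_int,
                "maf_external": maf_ext,
                "carriers": ";".join(sorted(c.carrier_ids)),
                "phase": c.phase,
            }
        )
    rows.sort(key=lambda r: r.pop("_sort") if "_sort" in r else ())
    for r in rows:
        r.pop("_sort", None)
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in CANDIDATE_COLUMNS) + "\n")


def read_frequency_table(path: str | Path) -> dict[tuple[str, int, str, str], "object"]:
    """Read a TSV of per-variant allele frequencies.

    Columns: chrom, pos, ref, alt, maf_internal, maf_external (empty allowed).
    Returns a dict keyed by (chrom, pos, ref, alt); values have
    ``maf_internal`` / ``maf_external`` attributes (``None`` when absent).
    """
    from .variant_prioritization import FrequencyRecord  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    out: dict[tuple[str, int, str, str], FrequencyRecord] = {}
    for row in df.itertuples(index=False):
        ext = getattr(row, "maf_external", None)
        ext = None if ext is None or pd.isna(ext) else float(ext)
        internal = None if pd.isna(row.maf_internal) else float(row.maf_internal)
        out[(str(row.chrom), int(row.pos), row.ref, row.alt)] = FrequencyRecord(
            maf_internal=internal, maf_external=ext
        )
    return out


def write_frequency_table(freqs: Mapping[tuple[str, int, str, str], "object"], path: str | Path) -> None:
    rows = []
    for (chrom, pos, ref, alt), f in sorted(freqs.items()):
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "maf_internal": f.maf_internal,
                "maf_external": "" if f.maf_external is None else f.maf_external,
            }
        )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf_internal", "maf_external"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: id, case_status, trait columns, sex, age, region."""
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def read_flow_events(path: str | Path) -> pd.DataFrame:
    """Flow-event TSV: sample_id, condition (unstimulated|PMA), intensity."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    bad = set(df["condition"]) - {"unstimulated", "PMA"}
    if bad:
        raise ValueError(f"unknown flow conditions: {sorted(bad)}")
    return df
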