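"""Core variant and cohort record types, TSV I/O, and the study-level filters/tallies.

The unit of analysis is a coding variant observed in a sequenced individual,
annotated with an effect class and an inheritance call.  Likely gene-disrupting
(LGD) variants are stopgains, frameshifts and canonical splice-site mutations —
the classes expected to truncate or abolish the protein product.  Effect
classification itself is an *input* (as produced by annotation tools such as
ANNOVAR); this module only normalizes vocabulary, filters, and tallies.

Tabular formats are plain TSV so every table can be inspected and versioned:

* variant table — required columns ``individual_id, role, cohort, gene, effect,
  inheritance``; optional ``nt_change, aa_change, ref_pop_maf, low_confidence,
  chrom, pos, ref, alt``.
* cohort-size table — ``cohort, size``.
* individuals table — ``individual_id, role, cohort, paternal_age``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "Inheritance",
    "DeNovoVariant",
    "CohortTable",
    "GeneRecord",
    "LGD_EFFECTS",
    "is_lgd",
    "read_variant_table",
    "write_variant_table",
    "read_cohort_table",
    "read_gene_table",
    "write_gene_table",
    "read_gene_list",
    "filter_variants",
    "tally_inheritance",
    "cohort_size_accounting",
    "count_events_per_individual",
    "count_events_per_gene",
]


class Effect(str, Enum):
    """Closed vocabulary of coding-variant effect classes."""

    STOPGAIN = "stopgain"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Inheritance(str, Enum):
    DE_NOVO = "de_novo"
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    UNDETERMINED = "undetermined"


#: LGD = likely gene-disrupting: the protein-truncating effect classes.
LGD_EFFECTS = frozenset({Effect.STOPGAIN, Effect.FRAMESHIFT, Effect.SPLICE_SITE})

# Center-specific synonyms normalized into the closed vocabulary.  Unknown
# strings map to OTHER rather than raising: upstream annotation pipelines emit
# open-ended terms and a row must never be silently dropped at parse time.
_EFFECT_ALIASES: dict[str, Effect] = {
    "stopgain": Effect.STOPGAIN,
    "stop_gained": Effect.STOPGAIN,
    "stop gained": Effect.STOPGAIN,
    "nonsense": Effect.STOPGAIN,
    "sg": Effect.STOPGAIN,
    "frameshift": Effect.FRAMESHIFT,
    "frameshift_variant": Effect.FRAMESHIFT,
    "frameshift indel": Effect.FRAMESHIFT,
    "fs": Effect.FRAMESHIFT,
    "splice_site": Effect.SPLICE_SITE,
    "splice site": Effect.SPLICE_SITE,
    "splice-site": Effect.SPLICE_SITE,
    "splice_donor_variant": Effect.SPLICE_SITE,
    "splice_acceptor_variant": Effect.SPLICE_SITE,
    "splicing": Effect.SPLICE_SITE,
    "sp": Effect.SPLICE_SITE,
    "missense": Effect.MISSENSE,
    "missense_variant": Effect.MISSENSE,
    "nonsynonymous": Effect.MISSENSE,
    "synonymous": Effect.SYNONYMOUS,
    "synonymous_variant": Effect.SYNONYMOUS,
    "silent": Effect.SYNONYMOUS,
}

_INHERITANCE_ALIASES: dict[str, Inheritance] = {
    "de_novo": Inheritance.DE_NOVO,
    "de novo": Inheritance.DE_NOVO,
    "denovo": Inheritance.DE_NOVO,
    "dn": Inheritance.DE_NOVO,
    "paternal": Inheritance.PATERNAL,
    "maternal": Inheritance.MATERNAL,
    "inherited_paternal": Inheritance.PATERNAL,
    "inherited_maternal": Inheritance.MATERNAL,
    "undetermined": Inheritance.UNDETERMINED,
    "unknown": Inheritance.UNDETERMINED,
}


def normalize_effect(label: str) -> Effect:
    """Map a free-text effect label onto the closed vocabulary (unknown -> other)."""
    return _EFFECT_ALIASES.get(str(label).strip().lower(), Effect.OTHER)


def normalize_inheritance(label: str) -> Inheritance:
    key = str(label).strip().lower()
    if key in _INHERITANCE_ALIASES:
        return _INHERITANCE_ALIASES[key]
    raise ValueError(f"unrecognized inheritance label: {label!r}")


@dataclass(frozen=True)
class DeNovoVariant:
    """One observed coding variant in one carrier.

    ``site_key`` is the canonical position key used for recurrence detection:
    ``chrom:pos:ref:alt`` (1-based, VCF convention) when coordinates are
    available, otherwise ``gene:nt_change``.  HGVS strings are opaque labels
    and are never parsed.
    """

    individual_id: str
    gene: str
    effect: Effect
    inheritance: Inheritance
    nt_change: str = ""
    aa_change: str = ""
    ref_pop_maf: float | None = None
    low_confidence: bool = False
    role: str = "proband"
    cohort: str = ""
    chrom: str = ""
    pos: int | None = None
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.ref_pop_maf is not None and not (0.0 <= self.ref_pop_maf <= 1.0):
            raise ValueError(f"ref_pop_maf outside [0, 1]: {self.ref_pop_maf}")
        if not self.site_key:
            raise ValueError("variant has neither coordinates nor gene/nt_change")

    @property
    def site_key(self) -> str:
        if self.chrom and self.pos is not None and self.ref and self.alt:
            return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
        return f"{self.gene}:{self.nt_change}" if (self.gene or self.nt_change) else ""

    @property
    def family_id(self) -> str:
        """Family identifier: the individual id up to the first '.' separator."""
        return self.individual_id.split(".")[0]


@dataclass
class CohortTable:
    """Individuals with role/cohort/paternal age, plus per-cohort tested counts.

    ``cohort_sizes`` maps cohort name to the number of tested individuals it
    contributed to the screen; cohorts of unknown size are simply absent.
    """

    individuals: list[tuple[str, str, str, float | None]] = field(default_factory=list)
    cohort_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, size in self.cohort_sizes.items():
            if int(size) <= 0:
                raise ValueError(f"cohort {name!r} has non-positive size {size}")
        for _, role, _, _ in self.individuals:
            if role not in ("proband", "sibling"):
                raise ValueError(f"unknown role {role!r}")

    @property
    def individual_cohort(self) -> dict[str, str]:
        return {iid: cohort for iid, _, cohort, _ in self.individuals}

    @property
    def individual_role(self) -> dict[str, str]:
        return {iid: role for iid, role, _, _ in self.individuals}

    @property
    def paternal_ages(self) -> dict[str, float | None]:
        return {iid: age for iid, _, _, age in self.individuals}

    def ids_with_role(self, role: str) -> list[str]:
        return [iid for iid, r, _, _ in self.individuals if r == role]


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene annotation: constraint, mutation-rate parameters, set membership.

    * ``pli`` — probability of loss-of-function intolerance, in [0, 1]
      (higher = more intolerant).
    * ``rvis_pct`` — residual variation intolerance score percentile, in
      [0, 100] (lower = more intolerant).
    * ``rel_rate_ch`` — the gene's share of the genome-wide LGD mutation rate
      under the divergence-calibrated (CH) model, a fraction in (0, 1).
    * ``mu_lgd`` — per-gene LGD mutation probability per haploid genome per
      generation, from trinucleotide-context rates.
    """

    gene: str
    pli: float | None = None
    rvis_pct: float | None = None
    rel_rate_ch: float | None = None
    mu_lgd: float | None = None
    fmrp_target: bool = False
    rbfox_target: bool = False
    brain_expressed: bool = True
    known_significant: bool = False

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pli outside [0, 1]: {self.pli}")
        if self.rvis_pct is not None and not (0.0 <= self.rvis_pct <= 100.0):
            raise ValueError(f"rvis_pct outside [0, 100]: {self.rvis_pct}")
        if self.rel_rate_ch is not None and self.rel_rate_ch <= 0:
            raise ValueError("rel_rate_ch must be positive")
        if self.mu_lgd is not None and self.mu_lgd <= 0:
            raise ValueError("mu_lgd must be positive")


def is_lgd(v: DeNovoVariant) -> bool:
    """True iff the variant's effect class is likely gene-disrupting."""
    return v.effect in LGD_EFFECTS


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_VARIANT_COLUMNS = ("individual_id", "role", "cohort", "gene", "effect", "inheritance")
_OPTIONAL_VARIANT_COLUMNS = (
    "nt_change",
    "aa_change",
    "ref_pop_maf",
    "low_confidence",
    "chrom",
    "pos",
    "ref",
    "alt",
)


class TableFormatError(ValueError):
    """A tabular input does not conform to the documented column contract."""


def _parse_bool(x: object) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    return s in ("1", "true", "t", "yes", "y")


def read_variant_table(path: str | Path) -> list[DeNovoVariant]:
    """Read a variant TSV into records.

    Unknown effect strings map to :attr:`Effect.OTHER`; an empty/NA MAF field
    parses as missing.  A missing required column raises
    :class:`TableFormatError` naming the column; an unparseable row raises a
    ``ValueError`` carrying the 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in _REQUIRED_VARIANT_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"variant table {path} is missing required column {col!r}")
    out: list[DeNovoVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        try:
            maf_raw = r.get("ref_pop_maf")
            maf = None if maf_raw is None or pd.isna(maf_raw) or str(maf_raw) == "" else float(maf_raw)
            pos_raw = r.get("pos")
            pos = None if pos_raw is None or pd.isna(pos_raw) or str(pos_raw) == "" else int(float(pos_raw))

            def _s(key: str) -> str:
                val = r.get(key)
                return "" if val is None or pd.isna(val) else str(val)

            out.append(
                DeNovoVariant(
                    individual_id=_s("individual_id"),
                    role=_s("role") or "proband",
                    cohort=_s("cohort"),
                    gene=_s("gene"),
                    effect=normalize_effect(_s("effect")),
                    inheritance=normalize_inheritance(_s("inheritance")),
                    nt_change=_s("nt_change"),
                    aa_change=_s("aa_change"),
                    ref_pop_maf=maf,
                    low_confidence=_parse_bool(r.get("low_confidence", False))
                    if r.get("low_confidence") is not None and not pd.isna(r.get("low_confidence"))
                    else False,
                    chrom=_s("chrom"),
                    pos=pos,
                    ref=_s("ref"),
                    alt=_s("alt"),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cannot parse variant table row {i}: {exc}") from exc
    return out


def variants_to_frame(vs: Iterable[DeNovoVariant]) -> pd.DataFrame:
    rows = []
    for v in vs:
        rows.append(
            {
                "individual_id": v.individual_id,
                "role": v.role,
                "cohort": v.cohort,
                "gene": v.gene,
                "effect": v.effect.value,
                "inheritance": v.inheritance.value,
                "nt_change": v.nt_change,
                "aa_change": v.aa_change,
                "ref_pop_maf": "" if v.ref_pop_maf is None else repr(v.ref_pop_maf),
                "low_confidence": str(v.low_confidence).lower(),
                "chrom": v.chrom,
                "pos": "" if v.pos is None else str(v.pos),
                "ref": v.ref,
                "alt": v.alt,
            }
        )
    cols = list(_REQUIRED_VARIANT_COLUMNS) + list(_OPTIONAL_VARIANT_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def write_variant_table(vs: Iterable[DeNovoVariant], path: str | Path) -> None:
    """Write records as TSV with a stable column order (round-trip safe)."""
    variants_to_frame(vs).to_csv(path, sep="\t", index=False)


def read_cohort_table(sizes_path: str | Path | None, individuals_path: str | Path | None = None) -> CohortTable:
    """Read the cohort-size TSV and (optionally) the individuals TSV."""
    sizes: dict[str, int] = {}
    if sizes_path is not None:
        sdf = pd.read_csv(sizes_path, sep="\t", dtype=str, comment="#")
        for col in ("cohort", "size"):
            if col not in sdf.columns:
                raise TableFormatError(f"cohort table {sizes_path} is missing required column {col!r}")
        for _, row in sdf.iterrows():
            raw = row["size"]
            if raw is None or pd.isna(raw) or str(raw).strip() in ("", "-", "NA"):
                continue
            sizes[str(row["cohort"])] = int(float(raw))
    individuals: list[tuple[str, str, str, float | None]] = []
    if individuals_path is not None:
        idf = pd.read_csv(individuals_path, sep="\t", dtype=str, comment="#")
        for col in ("individual_id", "role", "cohort"):
            if col not in idf.columns:
                raise TableFormatError(f"individuals table {individuals_path} is missing required column {col!r}")
        for _, row in idf.iterrows():
            age_raw = row.get("paternal_age")
            age = None if age_raw is None or pd.isna(age_raw) or str(age_raw) == "" else float(age_raw)
            individuals.append((str(row["individual_id"]), str(row["role"]), str(row["cohort"]), age))
    return CohortTable(individuals=individuals, cohort_sizes=sizes)


def read_gene_table(path: str | Path) -> dict[str, GeneRecord]:
    """Read per-gene annotation TSV keyed by symbol.

    Expected columns: ``gene`` plus any of ``pli, rvis_pct, rel_rate_ch,
    mu_lgd, fmrp_target, rbfox_target, brain_expressed, known_significant``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "gene" not in df.columns:
        raise TableFormatError(f"gene table {path} is missing required column 'gene'")

    def _f(row: pd.Series, key: str) -> float | None:
        val = row.get(key)
        if val is None or pd.isna(val) or str(val).strip() in ("", "-", "NA"):
            return None
        return float(val)

    records: dict[str, GeneRecord] = {}
    for _, row in df.iterrows():
        g = str(row["gene"])
        records[g] = GeneRecord(
            gene=g,
            pli=_f(row, "pli"),
            rvis_pct=_f(row, "rvis_pct"),
            rel_rate_ch=_f(row, "rel_rate_ch"),
            mu_lgd=_f(row, "mu_lgd"),
            fmrp_target=_parse_bool(row.get("fmrp_target", False)),
            rbfox_target=_parse_bool(row.get("rbfox_target", False)),
            brain_expressed=_parse_bool(row.get("brain_expressed", True)),
            known_significant=_parse_bool(row.get("known_significant", False)),
        )
    return records


def write_gene_table(records: Mapping[str, GeneRecord], path: str | Path) -> None:
    rows = []
    for g in records.values():
        rows.append(
            {
                "gene": g.gene,
                "pli": "" if g.pli is None else repr(g.pli),
                "rvis_pct": "" if g.rvis_pct is None else repr(g.rvis_pct),
                "rel_rate_ch": "" if g.rel_rate_ch is None else repr(g.rel_rate_ch),
                "mu_lgd": "" if g.mu_lgd is None else repr(g.mu_lgd),
                "fmrp_target": str(g.fmrp_target).lower(),
                "rbfox_target": str(g.rbfox_target).lower(),
                "brain_expressed": str(g.brain_expressed).lower(),
                "known_significant": str(g.known_significant).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; '#' starts a comment."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.add(sym)
    return out


# ---------------------------------------------------------------------------
# Filters and tallies
# ---------------------------------------------------------------------------


def filter_variants(
    vs: Sequence[DeNovoVariant],
    maf_threshold: float = 0.001,
    drop_low_confidence_recurrent: bool = True,
) -> list[DeNovoVariant]:
    """Apply the population-frequency and recurrence-artifact filters.

    A variant is removed when its reference-population MAF is *strictly*
    greater than ``maf_threshold`` (a missing MAF — i.e. absent from the
    reference population — is always retained).  With
    ``drop_low_confidence_recurrent``, variants whose site recurs in more than
    one distinct family AND that are flagged low-confidence upstream are also
    removed: site recurrence alone is biology (the same splice-donor hit can
    arise independently), recurrence plus a low-confidence call is the batch
    artifact signature.  Order-preserving and idempotent.
    """
    if not (0.0 <= maf_threshold <= 1.0):
        raise ValueError("maf_threshold must be in [0, 1]")
    kept = [v for v in vs if v.ref_pop_maf is None or v.ref_pop_maf <= maf_threshold]
    if drop_low_confidence_recurrent:
        families_per_site: dict[str, set[str]] = {}
        for v in kept:
            families_per_site.setdefault(v.site_key, set()).add(v.family_id)
        kept = [
            v
            for v in kept
            if not (v.low_confidence and len(families_per_site[v.site_key]) > 1)
        ]
    return kept


def tally_inheritance(
    vs: Iterable[DeNovoVariant],
    classes: frozenset[Effect] | set[Effect] = LGD_EFFECTS,
) -> dict[Inheritance, int]:
    """Count qualifying variants per inheritance class (default: LGD classes)."""
    counts = {inh: 0 for inh in Inheritance}
    for v in vs:
        if v.effect in classes:
            counts[v.inheritance] += 1
    return counts


def cohort_size_accounting(
    vs: Iterable[DeNovoVariant],
    cohorts: CohortTable,
    restrict_inheritance: Iterable[Inheritance] | None = None,
    classes: frozenset[Effect] | set[Effect] = LGD_EFFECTS,
) -> tuple[int, int]:
    """Count carrier probands with a known cohort size and the total screened.

    Returns ``(n_probands_with_known_size, total_tested)`` where
    ``total_tested`` sums each contributing cohort's size exactly once no
    matter how many carrier probands it contributes.  A proband whose cohort
    has no stated size is excluded with a logged warning.
    """
    allowed = None if restrict_inheritance is None else set(restrict_inheritance)
    id_to_cohort = cohorts.individual_cohort
    probands: set[str] = set()
    contributing: set[str] = set()
    for v in vs:
        if v.effect not in classes:
            continue
        if allowed is not None and v.inheritance not in allowed:
            continue
        if v.role != "proband":
            continue
        cohort = id_to_cohort.get(v.individual_id, v.cohort)
        if not cohort:
            logger.warning("proband %s has no cohort mapping; excluded from accounting", v.individual_id)
            continue
        if cohort not in cohorts.cohort_sizes:
            logger.warning("cohort %r has no stated size; proband %s excluded", cohort, v.individual_id)
            continue
        probands.add(v.individual_id)
        contributing.add(cohort)
    total = sum(cohorts.cohort_sizes[c] for c in contributing)
    return len(probands), total


def count_events_per_individual(
    vs: Iterable[DeNovoVariant],
    individual_ids: Sequence[str],
    classes: frozenset[Effect] | set[Effect] = LGD_EFFECTS,
    inheritance: Inheritance | None = Inheritance.DE_NOVO,
) -> dict[str, int]:
    """Qualifying-event counts for every listed individual (zeros included)."""
    counts = {iid: 0 for iid in individual_ids}
    for v in vs:
        if v.effect not in classes:
            continue
        if inheritance is not None and v.inheritance != inheritance:
            continue
        if v.individual_id in counts:
            counts[v.individual_id] += 1
    return counts


def count_events_per_gene(
    vs: Iterable[DeNovoVariant],
    classes: frozenset[Effect] | set[Effect] = LGD_EFFECTS,
    inheritance: Inheritance | None = Inheritance.DE_NOVO,
    role: str | None = "proband",
) -> dict[str, int]:
    """Qualifying-event counts per gene (LGD + de novo in probands by default)."""
    counts: dict[str, int] = {}
    for v in vs:
        if v.effect not in classes:
            continue
        if inheritance is not None and v.inheritance != inheritance:
            continue
        if role is not None and v.role != role:
            continue
        counts[v.gene] = counts.get(v.gene, 0) + 1
    return counts
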