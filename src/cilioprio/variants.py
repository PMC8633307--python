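"""Rare putative pathogenic variant filtering and recessive candidate detection.

The filter cascade classifies annotated single-nucleotide / indel variants in
three ordered rules:

1. **frequency** — the variant must be rare (< ``af_max``) in every population
   database where it is reported (1000 Genomes, ExAC, ESP6500, gnomAD, CG46).
   A variant absent from all databases counts as rare.
2. **consequence / conservation** — only amino-acid-changing variants are
   retained.  Truncating consequences (stopgain, stoploss, frameshift,
   splicing) are kept outright; non-truncating amino-acid-changing variants
   (missense) must additionally sit at a conserved position
   (GERP > ``gerp_min``).
3. **pathogenicity** — for missense variants an M-CAP score above
   ``mcap_auto_keep`` keeps the variant automatically; scores in the gray zone
   [``mcap_gray_low``, ``mcap_auto_keep``] require at least
   ``min_deleterious_votes`` prediction tools calling the variant deleterious
   or highly pathogenic; scores below the gray zone are dropped.  A missing
   M-CAP score falls back to the tool vote.

Variants that survive the cascade feed recessive genotype detection: per
(sample, gene), a homozygous kept variant or at least two distinct kept
heterozygous variants (an unphased compound-heterozygous call) nominate the
gene as a recessive candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Consequence",
    "Genotype",
    "ToolCall",
    "AnnotatedVariant",
    "FilterConfig",
    "FilterVerdict",
    "RecessiveCandidate",
    "GenePanel",
    "classify_variant",
    "filter_table",
    "find_recessive_candidates",
    "intersect_panel",
    "variants_to_frame",
    "variants_from_frame",
    "read_variant_table",
    "write_variant_table",
]

AF_FIELDS = ("af_1000g", "af_exac", "af_esp6500", "af_gnomad", "af_cg46")

PREDICTION_TOOLS = (
    "SIFT",
    "PolyPhen2_HDIV",
    "PolyPhen2_HVAR",
    "MutationTaster",
    "MutationAssessor",
)


class Consequence(str, Enum):
    missense = "missense"
    stopgain = "stopgain"
    stoploss = "stoploss"
    frameshift = "frameshift"
    splicing = "splicing"
    synonymous = "synonymous"
    other = "other"


TRUNCATING = frozenset(
    {Consequence.stopgain, Consequence.stoploss, Consequence.frameshift, Consequence.splicing}
)
AA_CHANGING = TRUNCATING | {Consequence.missense}


class Genotype(str, Enum):
    het = "het"
    hom_alt = "hom_alt"


class ToolCall(str, Enum):
    deleterious = "deleterious"
    highly_pathogenic = "highly_pathogenic"
    tolerated = "tolerated"
    unknown = "unknown"


DAMAGING_CALLS = frozenset({ToolCall.deleterious, ToolCall.highly_pathogenic})


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant observed in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    sample_id: str
    genotype: Genotype
    af_1000g: float | None = None
    af_exac: float | None = None
    af_esp6500: float | None = None
    af_gnomad: float | None = None
    af_cg46: float | None = None
    gerp: float | None = None
    mcap: float | None = None
    tool_calls: Mapping[str, ToolCall] = field(default_factory=dict)
    clinvar: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not isinstance(self.genotype, Genotype):
            raise ValueError(f"genotype missing or invalid: {self.genotype!r}")
        for name in AF_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")

    @property
    def is_truncating(self) -> bool:
        return self.consequence in TRUNCATING

    @property
    def is_amino_acid_changing(self) -> bool:
        return self.consequence in AA_CHANGING

    @property
    def frequencies(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in AF_FIELDS}

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the rare putative pathogenic variant cascade.

    Comparisons are strict ("lower than", "higher than"); the M-CAP gray zone
    is closed at both ends.
    """

    af_max: float = 0.01
    gerp_min: float = 2.0
    mcap_auto_keep: float = 0.6
    mcap_gray_low: float = 0.025
    min_deleterious_votes: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.af_max < 1.0):
            raise ValueError("af_max must be in (0, 1)")
        if not (0.0 < self.mcap_gray_low < self.mcap_auto_keep <= 1.0):
            raise ValueError("need 0 < mcap_gray_low < mcap_auto_keep <= 1")
        if self.min_deleterious_votes < 1:
            raise ValueError("min_deleterious_votes must be >= 1")


class FailedRule(str, Enum):
    frequency = "frequency"
    not_aa_changing = "not_aa_changing"
    conservation = "conservation"
    pathogenicity = "pathogenicity"
    none = "none"


@dataclass(frozen=True)
class FilterVerdict:
    variant: AnnotatedVariant
    kept: bool
    failed_rule: FailedRule
    audit: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        assert self.kept == (self.failed_rule is FailedRule.none)


def _damaging_votes(v: AnnotatedVariant) -> int:
    return sum(1 for call in v.tool_calls.values() if ToolCall(call) in DAMAGING_CALLS)


def classify_variant(v: AnnotatedVariant, cfg: FilterConfig | None = None) -> FilterVerdict:
    """Apply the three-rule cascade to one variant; return verdict with audit.

    The audit trail lists every rule evaluated in order with its outcome, so
    that any reordering of the cascade would be observable downstream.
    """
    cfg = cfg or FilterConfig()
    audit: list[tuple[str, str]] = []

    # Rule 1: rare in every database where reported (absent == rare).
    offending = [
        name for name, f in v.frequencies.items() if f is not None and f >= cfg.af_max
    ]
    if offending:
        audit.append(("frequency", f"fail:{','.join(offending)}"))
        return FilterVerdict(v, False, FailedRule.frequency, tuple(audit))
    audit.append(("frequency", "pass"))

    # Rule 2: amino-acid-changing; truncating auto-keep, else conservation gate.
    if not v.is_amino_acid_changing:
        audit.append(("consequence", f"fail:{v.consequence.value}"))
        return FilterVerdict(v, False, FailedRule.not_aa_changing, tuple(audit))
    if v.is_truncating:
        audit.append(("consequence", "pass:truncating_auto_keep"))
        return FilterVerdict(v, True, FailedRule.none, tuple(audit))
    audit.append(("consequence", "pass:missense"))
    if v.gerp is None or v.gerp <= cfg.gerp_min:
        audit.append(("conservation", f"fail:gerp={v.gerp}"))
        return FilterVerdict(v, False, FailedRule.conservation, tuple(audit))
    audit.append(("conservation", "pass"))

    # Rule 3: M-CAP / tool-vote pathogenicity gate for missense variants.
    votes = _damaging_votes(v)
    if v.mcap is None:
        if votes >= cfg.min_deleterious_votes:
            audit.append(("pathogenicity", f"pass:no_mcap_votes={votes}"))
            return FilterVerdict(v, True, FailedRule.none, tuple(audit))
        audit.append(("pathogenicity", f"fail:no_mcap_votes={votes}"))
        return FilterVerdict(v, False, FailedRule.pathogenicity, tuple(audit))
    if v.mcap > cfg.mcap_auto_keep:
        audit.append(("pathogenicity", "pass:mcap_auto_keep"))
        return FilterVerdict(v, True, FailedRule.none, tuple(audit))
    if v.mcap >= cfg.mcap_gray_low:
        if votes >= cfg.min_deleterious_votes:
            audit.append(("pathogenicity", f"pass:gray_votes={votes}"))
            return FilterVerdict(v, True, FailedRule.none, tuple(audit))
        audit.append(("pathogenicity", f"fail:gray_votes={votes}"))
        return FilterVerdict(v, False, FailedRule.pathogenicity, tuple(audit))
    audit.append(("pathogenicity", f"fail:mcap={v.mcap}"))
    return FilterVerdict(v, False, FailedRule.pathogenicity, tuple(audit))


def filter_table(
    variants: Sequence[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], list[FilterVerdict], dict[str, int]]:
    """Classify every variant; return (kept, verdicts, per-rule summary counts).

    Summary counts partition the input: each variant is counted either under
    the rule that rejected it or under ``kept``.
    """
    cfg = cfg or FilterConfig()
    verdicts = [classify_variant(v, cfg) for v in variants]
    kept = [vd.variant for vd in verdicts if vd.kept]
    summary = {rule.value: 0 for rule in FailedRule if rule is not FailedRule.none}
    summary["kept"] = 0
    for vd in verdicts:
        if vd.kept:
            summary["kept"] += 1
        else:
            summary[vd.failed_rule.value] += 1
    return kept, verdicts, summary


class Mechanism(str, Enum):
    compound_het = "compound_het"
    homozygous = "homozygous"


@dataclass(frozen=True)
class RecessiveCandidate:
    sample_id: str
    gene: str
    mechanism: Mechanism
    variants: tuple[AnnotatedVariant, ...]

    def __post_init__(self) -> None:
        if self.mechanism is Mechanism.compound_het and len(self.variants) < 2:
            raise ValueError("compound_het needs >= 2 variants")
        if not self.variants:
            raise ValueError("candidate needs >= 1 variant")


def find_recessive_candidates(
    kept: Sequence[AnnotatedVariant], panel_samples: set[str] | None = None
) -> list[RecessiveCandidate]:
    """Detect recessive genotypes among cascade-surviving variants.

    Per (sample, gene): any homozygous-alt kept variant yields a homozygous
    candidate; two or more distinct heterozygous kept variants yield an
    (unphased) compound-heterozygous candidate.  Without parental genotypes
    the two hets may lie in cis, so compound-het calls can over-call.
    Output is sorted by (sample, gene, mechanism).
    """
    groups: dict[tuple[str, str], list[AnnotatedVariant]] = {}
    for v in kept:
        if panel_samples is not None and v.sample_id not in panel_samples:
            continue
        groups.setdefault((v.sample_id, v.gene), []).append(v)

    out: list[RecessiveCandidate] = []
    for (sample, gene), vs in sorted(groups.items()):
        homs = sorted((v for v in vs if v.genotype is Genotype.hom_alt), key=lambda v: v.key)
        hets = {v.key: v for v in vs if v.genotype is Genotype.het}
        if len(hets) >= 2:
            out.append(
                RecessiveCandidate(
                    sample, gene, Mechanism.compound_het,
                    tuple(sorted(hets.values(), key=lambda v: v.key)),
                )
            )
        if homs:
            out.append(RecessiveCandidate(sample, gene, Mechanism.homozygous, tuple(homs)))
    out.sort(key=lambda c: (c.sample_id, c.gene, c.mechanism.value))
    return out


@dataclass(frozen=True)
class GenePanel:
    """A named gene panel (e.g. the SYSCILIA cilia gene list)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel must be nonempty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GenePanel":
        """Read one symbol per line; '#' starts a comment."""
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    genes.append(line)
        return cls(name or str(path), frozenset(genes))


def intersect_panel(entries: Iterable, panel: GenePanel) -> list:
    """Keep only candidates / variants whose gene symbol is in the panel."""
    if not panel.genes:
        raise ValueError("empty gene panel")
    return [e for e in entries if e.gene.upper() in panel.genes]


# ---------------------------------------------------------------------------
# Tabular I/O — one row per variant per sample, fixed column names.

_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "sample_id", "genotype",
    *AF_FIELDS, "gerp", "mcap", *PREDICTION_TOOLS, "clinvar",
]


def variants_to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "consequence": v.consequence.value,
            "sample_id": v.sample_id, "genotype": v.genotype.value,
            "gerp": v.gerp, "mcap": v.mcap, "clinvar": v.clinvar,
        }
        row.update({name: getattr(v, name) for name in AF_FIELDS})
        for tool in PREDICTION_TOOLS:
            row[tool] = ToolCall(v.tool_calls.get(tool, ToolCall.unknown)).value
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def variants_from_frame(df: pd.DataFrame) -> list[AnnotatedVariant]:
    out = []
    for rec in df.to_dict("records"):
        def _num(x):
            return None if pd.isna(x) else float(x)

        out.append(
            AnnotatedVariant(
                chrom=str(rec["chrom"]), pos=int(rec["pos"]),
                ref=str(rec["ref"]), alt=str(rec["alt"]), gene=str(rec["gene"]),
                consequence=Consequence(rec["consequence"]),
                sample_id=str(rec["sample_id"]), genotype=Genotype(rec["genotype"]),
                **{name: _num(rec.get(name)) for name in AF_FIELDS},
                gerp=_num(rec.get("gerp")), mcap=_num(rec.get("mcap")),
                tool_calls={
                    t: ToolCall(rec.get(t, "unknown")) for t in PREDICTION_TOOLS
                },
                clinvar="" if pd.isna(rec.get("clinvar")) else str(rec.get("clinvar", "")),
            )
        )
    return out


def read_variant_table(path) -> list[AnnotatedVariant]:
    return variants_from_frame(pd.read_csv(path, sep="\t"))


def write_variant_table(variants: Sequence[AnnotatedVariant], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def verdicts_to_frame(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    rows = []
    for vd in verdicts:
        v = vd.variant
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "sample_id": v.sample_id,
                "kept": vd.kept, "failed_rule": vd.failed_rule.value,
                "audit": ";".join(f"{r}={o}" for r, o in vd.audit),
            }
        )
    return pd.DataFrame(rows)


def candidates_to_frame(cands: Sequence[RecessiveCandidate]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id, "gene": c.gene, "mechanism": c.mechanism.value,
            "n_variants": len(c.variants),
            "variants": ";".join(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in c.variants),
        }
        for c in cands
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "mechanism", "n_variants", "variants"]
    )
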