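"""Genome annotation data model and readers/writers for standard formats.

All coordinates are held internally as 0-based half-open intervals; GFF3
(1-based inclusive) is converted at the file boundary in both directions, so
distance arithmetic downstream never needs an off-by-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
from Bio import SeqIO
from gffutils.feature import feature_from_line

REPEAT_CLASSES = ("LTR", "DNA", "non-LTR", "unclassified", "other")


class Gff3ParseError(ValueError):
    """Raised for a malformed GFF3 record, naming the offending line."""


@dataclass(frozen=True)
class GeneFeature:
    """A gene model on a scaffold (0-based half-open coordinates)."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.protein_length is not None and self.protein_length < 1:
            raise ValueError(f"gene {self.gene_id}: protein_length must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat / transposable-element annotation (0-based half-open)."""

    repeat_id: str
    scaffold_id: str
    start: int
    end: int
    repeat_class: str = "other"

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"repeat {self.repeat_id}: end ({self.end}) must exceed start "
                f"({self.start})"
            )
        if self.repeat_class not in REPEAT_CLASSES:
            object.__setattr__(self, "repeat_class", "other")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Per-gene functional flags consumed (not computed) by the pipeline."""

    gene_id: str
    is_secreted: bool = False
    cazy_family: str | None = None
    is_lipase_or_protease: bool = False
    kog_category: str | None = None


@dataclass(frozen=True)
class ScaffoldSimilarityPair:
    """Nucleotide-level similarity between two scaffolds of one assembly."""

    scaffold_a: str
    scaffold_b: str
    coverage_fraction: float
    identity_fraction: float

    def __post_init__(self) -> None:
        if self.scaffold_a == self.scaffold_b:
            raise ValueError("a scaffold cannot be paired with itself")
        for name in ("coverage_fraction", "identity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class GenomeAnnotation:
    """Scaffolds, gene models and repeat annotations for one species.

    Invariants checked on :meth:`validate`: every feature lies on a known
    scaffold within its bounds, and gene ids are unique within the species.
    """

    species_id: str
    scaffolds: list[tuple[str, int]]
    genes: list[GeneFeature] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)

    def validate(self) -> "GenomeAnnotation":
        lengths = dict(self.scaffolds)
        if len(lengths) != len(self.scaffolds):
            raise ValueError(f"{self.species_id}: duplicate scaffold ids")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"{self.species_id}: duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
        for feat in (*self.genes, *self.repeats):
            if feat.scaffold_id not in lengths:
                raise ValueError(
                    f"{self.species_id}: feature on unknown scaffold {feat.scaffold_id}"
                )
            if not (0 <= feat.start < feat.end <= lengths[feat.scaffold_id]):
                raise ValueError(
                    f"{self.species_id}: feature [{feat.start}, {feat.end}) outside "
                    f"scaffold {feat.scaffold_id} of length {lengths[feat.scaffold_id]}"
                )
        return self

    def scaffold_length(self, scaffold_id: str) -> int:
        return dict(self.scaffolds)[scaffold_id]

    def genes_on(self, scaffold_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.scaffold_id == scaffold_id]

    def repeats_on(self, scaffold_id: str) -> list[RepeatFeature]:
        return [r for r in self.repeats if r.scaffold_id == scaffold_id]

    def restrict_to_scaffolds(self, keep: set[str]) -> "GenomeAnnotation":
        """A copy containing only features on the scaffolds in ``keep``."""
        return GenomeAnnotation(
            species_id=self.species_id,
            scaffolds=[s for s in self.scaffolds if s[0] in keep],
            genes=[g for g in self.genes if g.scaffold_id in keep],
            repeats=[r for r in self.repeats if r.scaffold_id in keep],
        )


# ---------------------------------------------------------------------------
# file I/O


def _classify_repeat(raw: str) -> str:
    token = raw.strip()
    lowered = token.lower()
    if lowered in {"ltr", "ltr_retrotransposon"} or lowered.startswith("ltr"):
        return "LTR"
    if lowered.startswith("dna") or "tir" in lowered:
        return "DNA"
    if lowered in {"non-ltr", "nonltr", "line", "sine"} or lowered.startswith("non-ltr"):
        return "non-LTR"
    if lowered in {"unclassified", "unknown"}:
        return "unclassified"
    return "other"


def read_gff3(
    path: str | Path, feature_kind: Literal["gene", "repeat"]
) -> list[GeneFeature] | list[RepeatFeature]:
    """Read gene or repeat features from a flat GFF3 file.

    1-based inclusive GFF3 coordinates are converted to 0-based half-open.
    Output is sorted by (scaffold, start, end, id).  For repeats the
    ``repeat_class`` attribute (or, failing that, the GFF3 type column) is
    mapped onto {LTR, DNA, non-LTR, unclassified}; anything unrecognized
    becomes "other".
    """
    if feature_kind not in ("gene", "repeat"):
        raise ValueError(f"feature_kind must be 'gene' or 'repeat', got {feature_kind!r}")
    out: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise Gff3ParseError(
                    f"line {lineno}: expected 9 tab-separated GFF3 columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several exception types
                raise Gff3ParseError(f"line {lineno}: malformed GFF3 record ({exc})")
            if feat.start is None or feat.end is None:
                raise Gff3ParseError(f"line {lineno}: missing start/end coordinate")
            if feat.end < feat.start:
                raise Gff3ParseError(
                    f"line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            attrs = feat.attributes
            feat_id = attrs.get("ID", [f"{feature_kind}_{lineno}"])[0]
            if feature_kind == "gene":
                plen = attrs.get("protein_length", [None])[0]
                out.append(
                    GeneFeature(
                        gene_id=feat_id,
                        scaffold_id=feat.seqid,
                        start=start,
                        end=end,
                        strand=feat.strand if feat.strand in "+-" else "+",
                        protein_length=int(plen) if plen is not None else None,
                    )
                )
            else:
                raw_class = attrs.get("repeat_class", [feat.featuretype])[0]
                out.append(
                    RepeatFeature(
                        repeat_id=feat_id,
                        scaffold_id=feat.seqid,
                        start=start,
                        end=end,
                        repeat_class=_classify_repeat(raw_class),
                    )
                )
    out.sort(key=lambda f: (f.scaffold_id, f.start, f.end, f.gene_id if feature_kind == "gene" else f.repeat_id))
    return out


def write_gff3(
    path: str | Path,
    features: Iterable[GeneFeature | RepeatFeature],
    source: str = "mycopan",
) -> None:
    """Write features as flat GFF3 (converting back to 1-based inclusive)."""
    feats = sorted(
        features,
        key=lambda f: (
            f.scaffold_id,
            f.start,
            f.end,
            f.gene_id if isinstance(f, GeneFeature) else f.repeat_id,
        ),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            if isinstance(f, GeneFeature):
                extra = (
                    f";protein_length={f.protein_length}"
                    if f.protein_length is not None
                    else ""
                )
                fh.write(
                    f"{f.scaffold_id}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.gene_id}{extra}\n"
                )
            else:
                fh.write(
                    f"{f.scaffold_id}\t{source}\tdispersed_repeat\t{f.start + 1}\t"
                    f"{f.end}\t.\t.\t.\tID={f.repeat_id};repeat_class={f.repeat_class}\n"
                )


def read_bed_repeats(path: str | Path) -> list[RepeatFeature]:
    """Read repeats from a BED file (>= 4 columns; BED is already 0-based).

    Column 4 is used as the repeat id; column 5 (if present and textual) or
    the id prefix as the repeat class.
    """
    out: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise Gff3ParseError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if end <= start:
                raise Gff3ParseError(f"line {lineno}: end ({end}) <= start ({start})")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else f"repeat_{lineno}"
            raw_class = cols[4] if len(cols) > 4 and not cols[4].isdigit() else name
            out.append(
                RepeatFeature(
                    repeat_id=name,
                    scaffold_id=chrom,
                    start=start,
                    end=end,
                    repeat_class=_classify_repeat(raw_class),
                )
            )
    out.sort(key=lambda r: (r.scaffold_id, r.start, r.end, r.repeat_id))
    return out


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Protein lengths per sequence id, excluding a trailing stop '*'."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq)
        if seq.endswith("*"):
            seq = seq[:-1]
        lengths[record.id] = len(seq)
    return lengths


def read_functional_annotations(path: str | Path) -> dict[str, FunctionalAnnotation]:
    """Read the functional-annotation TSV.

    Expected header:
    ``gene_id  is_secreted  cazy_family  is_lipase_or_protease  kog_category``
    with booleans as 0/1 or true/false and '.' / empty for missing text.
    """
    truthy = {"1", "true", "yes", "y"}
    out: dict[str, FunctionalAnnotation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "gene_id",
            "is_secreted",
            "cazy_family",
            "is_lipase_or_protease",
            "kog_category",
        ]
        if header != expected:
            raise ValueError(f"bad header {header}; expected {expected}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 5:
                raise ValueError(f"line {lineno}: expected 5 columns, got {len(cols)}")
            gene_id, secreted, cazy, lipo, kog = cols
            out[gene_id] = FunctionalAnnotation(
                gene_id=gene_id,
                is_secreted=secreted.lower() in truthy,
                cazy_family=cazy if cazy not in ("", ".") else None,
                is_lipase_or_protease=lipo.lower() in truthy,
                kog_category=kog if kog not in ("", ".") else None,
            )
    return out


def write_functional_annotations(
    path: str | Path, annotations: Iterable[FunctionalAnnotation]
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tis_secreted\tcazy_family\tis_lipase_or_protease\tkog_category\n")
        for fa in sorted(annotations, key=lambda a: a.gene_id):
            fh.write(
                f"{fa.gene_id}\t{int(fa.is_secreted)}\t{fa.cazy_family or '.'}\t"
                f"{int(fa.is_lipase_or_protease)}\t{fa.kog_category or '.'}\n"
            )


def select_primary_scaffolds(
    pairs: Iterable[ScaffoldSimilarityPair],
    lengths: dict[str, int],
    min_coverage: float = 0.50,
    min_identity: float = 0.90,
) -> set[str]:
    """Resolve allelic scaffolds, keeping the longest of each allelic group.

    Two scaffolds are allelic when their nucleotide similarity exceeds both
    thresholds (coverage > 0.5 and identity > 0.9 by default).  Allelic
    relations may chain (a~b, b~c); each connected component keeps exactly
    its single longest scaffold.  Scaffolds in no allelic pair are retained.
    """
    graph = nx.Graph()
    graph.add_nodes_from(lengths)
    for p in pairs:
        for sid in (p.scaffold_a, p.scaffold_b):
            if sid not in lengths:
                raise KeyError(f"similarity pair references unknown scaffold {sid!r}")
        if p.coverage_fraction > min_coverage and p.identity_fraction > min_identity:
            graph.add_edge(p.scaffold_a, p.scaffold_b)
    primary: set[str] = set()
    for component in nx.connected_components(graph):
        # longest scaffold wins; ties broken towards the smaller id
        best = sorted(component, key=lambda s: (-lengths[s], s))[0]
        primary.add(best)
    return primary
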