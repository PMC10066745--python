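"""Secretome and small-secreted-protein (SSP) classification.

Each gene is assigned to exactly one of five classes: secreted CAZyme,
secreted lipase/protease, SSP (secreted, < 300 aa), other secreted protein,
or non-secreted.  For disjoint uses (e.g. the TE-proximity gene classes) the
precedence CAZyme > lipase/protease > SSP > secreted_other applies, so an
SSP-sized CAZyme counts as a CAZyme.  Secretome summaries additionally count
the SSPs as a subcategory of the whole secretome, in which an SSP-sized
enzyme appears both in its enzyme column and in the SSP column.

Secretion, CAZyme and lipase/protease flags are inputs (produced upstream by
signal-peptide and domain annotation); this module only combines them.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from mycopan.annotation_io import FunctionalAnnotation, GenomeAnnotation

GENE_CLASSES = ("CAZyme", "lipase_protease", "SSP", "secreted_other", "non_secreted")


def classify_gene(
    fa: FunctionalAnnotation,
    protein_length: int | None,
    ssp_max_len: int = 300,
) -> str:
    """Assign the single (disjoint) gene class.

    SSP means secreted and strictly shorter than ``ssp_max_len`` amino acids
    (299 aa is an SSP; 300 aa is not).  Enzyme annotations take precedence,
    so a 150 aa secreted CAZyme is a CAZyme, not an SSP.
    """
    if not fa.is_secreted:
        return "non_secreted"
    if fa.cazy_family:
        return "CAZyme"
    if fa.is_lipase_or_protease:
        return "lipase_protease"
    if protein_length is None:
        raise ValueError(
            f"secreted gene {fa.gene_id} has no protein length; cannot test SSP rule"
        )
    if protein_length < ssp_max_len:
        return "SSP"
    return "secreted_other"


def classify_genes(
    annotations: Mapping[str, FunctionalAnnotation],
    lengths: Mapping[str, int],
    ssp_max_len: int = 300,
) -> dict[str, str]:
    """Disjoint class per gene id (genes without annotation are non_secreted)."""
    return {
        gid: classify_gene(fa, lengths.get(gid), ssp_max_len)
        for gid, fa in annotations.items()
    }


def secretome_summary(
    annotations_by_species: Mapping[str, Mapping[str, FunctionalAnnotation]],
    lengths_by_species: Mapping[str, Mapping[str, int]],
    ssp_max_len: int = 300,
) -> pd.DataFrame:
    """Per-species secretome composition.

    Columns: counts of secreted CAZymes, lipases/proteases, other secreted
    proteins, the total secretome, the SSP subcategory (every secreted
    protein under ``ssp_max_len`` aa, including SSP-sized enzymes) and the
    corresponding ratios to the total secretome.
    """
    rows = []
    for sp in sorted(annotations_by_species):
        annotations = annotations_by_species[sp]
        lengths = lengths_by_species[sp]
        n_cazy = n_lipo = n_other = n_ssp = 0
        for gid, fa in annotations.items():
            if not fa.is_secreted:
                continue
            length = lengths.get(gid)
            if length is None:
                raise ValueError(f"secreted gene {gid} has no protein length")
            if fa.cazy_family:
                n_cazy += 1
            elif fa.is_lipase_or_protease:
                n_lipo += 1
            else:
                n_other += 1
            if length < ssp_max_len:  # subcategory: enzymes included
                n_ssp += 1
        secretome = n_cazy + n_lipo + n_other
        rows.append(
            {
                "species_id": sp,
                "secretome": secretome,
                "cazymes": n_cazy,
                "lipases_proteases": n_lipo,
                "others": n_other,
                "ssp": n_ssp,
                "cazyme_ratio": n_cazy / secretome if secretome else 0.0,
                "lipase_protease_ratio": n_lipo / secretome if secretome else 0.0,
                "other_ratio": n_other / secretome if secretome else 0.0,
                "ssp_ratio": n_ssp / secretome if secretome else 0.0,
            }
        )
    return pd.DataFrame(rows)


def gene_length_by_class(
    annotation: GenomeAnnotation,
    class_map: Mapping[str, str],
    protein_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Median and quartiles of gene span (kb) and protein length (aa) per class.

    Classes without members are reported with NaN summaries rather than
    omitted, so downstream tables keep a fixed shape.
    """
    spans: dict[str, list[float]] = {c: [] for c in GENE_CLASSES}
    prots: dict[str, list[float]] = {c: [] for c in GENE_CLASSES}
    for g in annotation.genes:
        cls = class_map.get(g.gene_id)
        if cls not in spans:
            continue
        spans[cls].append(g.length / 1_000.0)
        plen = (
            protein_lengths.get(g.gene_id)
            if protein_lengths is not None
            else g.protein_length
        )
        if plen is not None:
            prots[cls].append(float(plen))
    rows = []
    for cls in GENE_CLASSES:
        span = np.array(spans[cls])
        prot = np.array(prots[cls])
        rows.append(
            {
                "gene_class": cls,
                "n_genes": span.size,
                "span_kb_q1": float(np.percentile(span, 25)) if span.size else np.nan,
                "span_kb_median": float(np.median(span)) if span.size else np.nan,
                "span_kb_q3": float(np.percentile(span, 75)) if span.size else np.nan,
                "protein_aa_median": float(np.median(prot)) if prot.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_classes_tsv(path, class_map: Mapping[str, str]) -> None:
    """`classes.tsv` (gene_id, gene_class) as consumed by the proximity stage."""
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_class\n")
        for gid in sorted(class_map):
            fh.write(f"{gid}\t{class_map[gid]}\n")


def read_classes_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["gene_id", "gene_class"]:
        raise ValueError("classes TSV must have columns gene_id, gene_class")
    return dict(zip(df.gene_id, df.gene_class))
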