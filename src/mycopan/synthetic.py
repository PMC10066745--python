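"""Synthetic multi-species genome, expression and isotope data with known truth.

The generator emulates the statistical structure a nine-genome comparative
study of ectomycorrhizal fungi assumes, at desk scale:

* protein families with a controlled core / accessory / species-specific
  pangenome structure and tunable within-family sequence identity;
* scaffold layouts of non-overlapping genes and uniformly placed repeats, in
  which one gene class (by default the SSPs) can be planted close to repeats;
* negative-binomial RNA count matrices with fold changes planted at
  per-pangenome-class rates;
* delta-13C triplets (host leaf / extraradical mycelium / free-living
  mycelium) generated from a two-pool mixing model with known mixing fraction.

Every generated entity carries its true label, and the whole module is
deterministic under a fixed seed: sub-streams are spawned from the master
seed by fixed offsets so each generator can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mycopan.annotation_io import GeneFeature, GenomeAnnotation, RepeatFeature

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

PARTITIONS = ("core", "accessory", "specific")
GENE_CLASSES = ("CAZyme", "lipase_protease", "SSP", "secreted_other", "non_secreted")

# fixed stream offsets so each sub-generator is independently reproducible
_STREAM = {"pangenome": 1, "layout": 2, "counts": 3, "isotopes": 4, "function": 5}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generator.

    Defaults mirror a nine-genome ECM fungal comparison at desk scale: nine
    species, a pangenome dominated by species-specific orthogroups, genes
    under 4 kb on repeat-rich scaffolds, triplicate RNA libraries per
    condition, and a pulse-labelled host leaf at strongly positive delta-13C
    against mycelium at natural abundance (~ -28 permil).
    """

    n_species: int = 9
    n_core: int = 25
    n_accessory: int = 35
    n_specific: int = 45
    ancestral_protein_length_range: tuple[int, int] = (120, 450)
    d: float = 0.10  # target expected within-family pairwise identity = 1 - d
    core_paralog_fraction: float = 0.0

    n_scaffolds: int = 4
    scaffold_length: int = 400_000
    n_repeats_per_scaffold: int = 15
    repeat_length_range: tuple[int, int] = (500, 5_000)
    n_genes_per_scaffold: int = 20
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "CAZyme": 0.05,
            "lipase_protease": 0.05,
            "SSP": 0.15,
            "secreted_other": 0.10,
            "non_secreted": 0.65,
        }
    )
    planted_proximity_class: str | None = "SSP"
    planted_proximity_max_dist: int = 2_000

    nb_mean_range: tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 0.05
    de_fraction_by_partition: dict[str, float] = field(
        default_factory=lambda: {"core": 0.15, "accessory": 0.10, "specific": 0.05}
    )
    lfc_magnitude: float = 2.0
    n_replicates: int = 3
    n_expression_species: int = 5  # transcriptomes are sequenced for a subset

    delta_leaf: float = 200.0  # permil, 13CO2 pulse-labelled host leaves
    delta_flm: float = -28.0  # permil, natural-abundance mycelium
    isotope_n: int = 6
    isotope_fraction: float = 0.35
    isotope_noise_sd: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_core, self.n_accessory, self.n_specific) < 0:
            raise ValueError("species and orthogroup counts must be >= 0")
        if not 0.0 <= self.d < 1.0:
            raise ValueError(f"d must lie in [0, 1), got {self.d}")
        if self.n_species < 2 and self.n_accessory > 0:
            raise ValueError("accessory orthogroups require at least 2 species")
        for part, p in self.de_fraction_by_partition.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"de_fraction_by_partition[{part!r}] not in [0, 1]")
        if self.planted_proximity_class is not None and (
            self.planted_proximity_class not in GENE_CLASSES
        ):
            raise ValueError(
                f"unknown planted class {self.planted_proximity_class!r}"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAM[stream], self.seed])

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


def _per_branch_substitution_prob(d: float) -> float:
    """Per-member substitution probability giving expected pairwise identity 1-d.

    Each family member is mutated independently from the ancestor with
    per-site probability p over a 20-letter alphabet (substitutions go to one
    of the 19 other residues uniformly).  Two members then match at a site
    with probability (1-p)^2 + p^2/19; p solves that expression = 1 - d.
    """
    if d == 0.0:
        return 0.0
    a = 1.0 + 1.0 / 19.0
    # a p^2 - 2 p + d = 0, take the root in [0, 1)
    return (2.0 - math.sqrt(4.0 - 4.0 * a * d)) / (2.0 * a)


def _mutate(ancestor: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions at rate p; hits move to one of the 19 other residues."""
    seq = ancestor.copy()
    hits = np.flatnonzero(rng.random(seq.size) < p)
    if hits.size:
        # draw from 19 alternatives by shifting past the current residue
        current = np.searchsorted(AMINO_ACIDS, seq[hits])
        offset = rng.integers(1, 20, size=hits.size)
        seq[hits] = AMINO_ACIDS[(current + offset) % 20]
    return seq


def simulate_pangenome(
    cfg: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Generate per-species proteomes with known orthogroup structure.

    Returns
    -------
    proteins:
        ``{species_id: {gene_id: sequence}}``.
    truth:
        DataFrame with columns og_id, species_id, gene_id, partition.
        Core families have a member in every species, accessory families in
        2..n_species-1 species, specific families in exactly one.
    """
    rng = cfg.rng("pangenome")
    p_sub = _per_branch_substitution_prob(cfg.d)
    species = cfg.species_ids
    lo, hi = cfg.ancestral_protein_length_range

    proteins: dict[str, dict[str, str]] = {s: {} for s in species}
    counters = {s: 0 for s in species}
    rows: list[tuple[str, str, str, str]] = []

    def members_for(partition: str, idx: int) -> list[str]:
        if partition == "core":
            return list(species)
        if partition == "specific":
            return [species[rng.integers(cfg.n_species)]]
        k = int(rng.integers(2, cfg.n_species))  # 2 .. n_species - 1
        chosen = rng.choice(cfg.n_species, size=k, replace=False)
        return [species[i] for i in sorted(chosen)]

    og_idx = 0
    for partition, n_fam in (
        ("core", cfg.n_core),
        ("accessory", cfg.n_accessory),
        ("specific", cfg.n_specific),
    ):
        for _ in range(n_fam):
            og_id = f"fam{og_idx:05d}"
            og_idx += 1
            length = int(rng.integers(lo, hi + 1))
            ancestor = AMINO_ACIDS[rng.integers(0, 20, size=length)]
            for sp in members_for(partition, og_idx):
                n_copies = 1
                if partition == "core" and rng.random() < cfg.core_paralog_fraction:
                    n_copies = 2
                for _copy in range(n_copies):
                    gene_id = f"{sp}_g{counters[sp]:05d}"
                    counters[sp] += 1
                    seq = _mutate(ancestor, p_sub, rng)
                    proteins[sp][gene_id] = seq.tobytes().decode("ascii")
                    rows.append((og_id, sp, gene_id, partition))

    if cfg.n_species == 1:
        # with a single genome every family is by definition species-specific
        rows = [(og, sp, g, "specific") for og, sp, g, _ in rows]

    truth = pd.DataFrame(rows, columns=["og_id", "species_id", "gene_id", "partition"])
    return proteins, truth


def _place_nonoverlapping(
    n: int,
    lengths: np.ndarray,
    scaffold_length: int,
    rng: np.random.Generator,
    fixed: list[tuple[int, int]] | None = None,
    max_tries: int = 1_000,
) -> list[int]:
    """Uniform starts for ``n`` intervals avoiding overlap with each other
    and with ``fixed`` intervals, by bounded rejection sampling."""
    placed: list[tuple[int, int]] = list(fixed or [])
    starts: list[int] = []
    for i in range(n):
        L = int(lengths[i])
        hi = scaffold_length - L
        if hi < 0:
            raise ValueError("gene longer than scaffold")
        for _try in range(max_tries):
            s = int(rng.integers(0, hi + 1))
            if all(s + L <= a or s >= b for a, b in placed):
                placed.append((s, s + L))
                starts.append(s)
                break
        else:
            raise RuntimeError(
                f"could not place interval of length {L} after {max_tries} tries; "
                "scaffold too crowded"
            )
    return starts


def _place_gap_method(
    lengths: np.ndarray, scaffold_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact uniform draw of non-overlapping starts (order-statistics gaps).

    Shuffle the gene order, draw n uniform points in [0, L - sum(lengths)],
    sort them, and offset by the cumulative lengths: uniform over all
    non-overlapping arrangements, and identical in distribution to the
    reshuffled null models of the proximity test.
    """
    n = lengths.size
    free = scaffold_length - int(lengths.sum())
    if free < 0:
        raise ValueError("genes exceed scaffold length")
    order = rng.permutation(n)
    gaps = np.sort(rng.integers(0, free + 1, size=n))
    starts_sorted = gaps + np.concatenate(([0], np.cumsum(lengths[order][:-1])))
    starts = np.empty(n, dtype=np.int64)
    starts[order] = starts_sorted
    return starts


def simulate_genome_layout(
    cfg: SimulationConfig,
    genes_by_species: dict[str, list[tuple[str, int, str]]] | None = None,
) -> tuple[dict[str, GenomeAnnotation], pd.DataFrame]:
    """Generate per-species scaffold layouts of genes and repeats.

    Repeats are placed uniformly and independently.  Background genes are
    placed uniformly without gene-gene overlap (genes may overlap repeats).
    When ``planted_proximity_class`` is set, genes of that class are instead
    anchored within ``planted_proximity_max_dist`` bp of a randomly chosen
    repeat edge, which plants a true "close to repeats" effect.

    By default each species receives ``n_genes_per_scaffold`` genes per
    scaffold with classes drawn from ``class_fractions``.  Alternatively an
    explicit gene universe can be supplied as
    ``{species: [(gene_id, genomic_length_bp, gene_class), ...]}`` (as the
    pipeline does with the pangenome genes), in which case genes are spread
    over the scaffolds at random.

    Returns the annotations plus a truth table (species_id, gene_id,
    gene_class, planted).
    """
    rng = cfg.rng("layout")
    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    rep_lo, rep_hi = cfg.repeat_length_range
    gene_lo, gene_hi = cfg.gene_length_range

    annotations: dict[str, GenomeAnnotation] = {}
    rows: list[tuple[str, str, str, bool]] = []

    species = cfg.species_ids if genes_by_species is None else sorted(genes_by_species)
    for sp in species:
        scaffolds = [
            (f"{sp}_scf{j + 1}", cfg.scaffold_length) for j in range(cfg.n_scaffolds)
        ]
        genes: list[GeneFeature] = []
        repeats: list[RepeatFeature] = []
        gene_n = 0
        # assign genes to scaffolds
        per_scaffold: dict[str, list[tuple[str, int, str]]] = {s: [] for s, _ in scaffolds}
        if genes_by_species is None:
            for scf_id, _ in scaffolds:
                cls_draw = rng.choice(len(classes), size=cfg.n_genes_per_scaffold, p=probs)
                len_draw = rng.integers(gene_lo, gene_hi + 1, size=cfg.n_genes_per_scaffold)
                for i in range(cfg.n_genes_per_scaffold):
                    per_scaffold[scf_id].append(
                        (f"{sp}_g{gene_n:05d}", int(len_draw[i]), classes[cls_draw[i]])
                    )
                    gene_n += 1
        else:
            scf_pick = rng.integers(0, cfg.n_scaffolds, size=len(genes_by_species[sp]))
            for (gid, glen, gcls), k in zip(genes_by_species[sp], scf_pick):
                per_scaffold[scaffolds[int(k)][0]].append((gid, glen, gcls))

        for scf_id, scf_len in scaffolds:
            rep_lengths = rng.integers(
                rep_lo, rep_hi + 1, size=cfg.n_repeats_per_scaffold
            )
            rep_starts = rng.integers(
                0, scf_len - rep_lengths + 1, size=cfg.n_repeats_per_scaffold
            )
            for k in range(cfg.n_repeats_per_scaffold):
                repeats.append(
                    RepeatFeature(
                        repeat_id=f"{scf_id}_r{k:04d}",
                        scaffold_id=scf_id,
                        start=int(rep_starts[k]),
                        end=int(rep_starts[k] + rep_lengths[k]),
                        repeat_class=str(
                            rng.choice(["LTR", "DNA", "non-LTR", "unclassified"])
                        ),
                    )
                )
            entries = per_scaffold[scf_id]
            if not entries:
                continue
            gene_lengths = np.array([e[1] for e in entries], dtype=np.int64)
            planted_mask = np.array(
                [
                    cfg.planted_proximity_class is not None
                    and e[2] == cfg.planted_proximity_class
                    for e in entries
                ]
            )
            placed: list[tuple[int, int]] = []
            starts = np.empty(len(entries), dtype=int)
            scf_repeats = [r for r in repeats if r.scaffold_id == scf_id]
            # planted genes first: anchor near a randomly chosen repeat edge
            for i in np.flatnonzero(planted_mask):
                L = int(gene_lengths[i])
                for _try in range(1_000):
                    rep = scf_repeats[rng.integers(len(scf_repeats))]
                    offset = int(rng.integers(0, cfg.planted_proximity_max_dist + 1))
                    if rng.random() < 0.5:
                        s = rep.end + offset  # downstream of the repeat
                    else:
                        s = rep.start - offset - L  # upstream of the repeat
                    if 0 <= s and s + L <= scf_len and all(
                        s + L <= a or s >= b for a, b in placed
                    ):
                        placed.append((s, s + L))
                        starts[i] = s
                        break
                else:
                    raise RuntimeError("could not place planted gene near a repeat")
            bg_idx = np.flatnonzero(~planted_mask)
            if placed:
                # planted genes are fixed obstacles: bounded rejection sampling
                starts[bg_idx] = _place_nonoverlapping(
                    bg_idx.size, gene_lengths[bg_idx], scf_len, rng, fixed=placed
                )
            else:
                # exact uniform arrangement, exchangeable with the null models
                starts[bg_idx] = _place_gap_method(
                    gene_lengths[bg_idx], scf_len, rng
                )
            for i, (gid, glen, gcls) in enumerate(entries):
                genes.append(
                    GeneFeature(
                        gene_id=gid,
                        scaffold_id=scf_id,
                        start=int(starts[i]),
                        end=int(starts[i] + glen),
                        strand="+" if rng.random() < 0.5 else "-",
                        protein_length=max(1, glen // 3),
                    )
                )
                rows.append((sp, gid, gcls, bool(planted_mask[i])))
        genes.sort(key=lambda g: (g.scaffold_id, g.start, g.gene_id))
        annotations[sp] = GenomeAnnotation(
            species_id=sp, scaffolds=scaffolds, genes=genes, repeats=repeats
        ).validate()

    truth = pd.DataFrame(rows, columns=["species_id", "gene_id", "gene_class", "planted"])
    return annotations, truth


def simulate_functional_annotations(
    cfg: SimulationConfig,
    lengths_by_species: dict[str, dict[str, int]],
    secreted_fraction: float = 0.30,
    cazyme_fraction: float = 0.15,
    lipase_protease_fraction: float = 0.10,
) -> dict[str, dict[str, "FunctionalAnnotation"]]:
    """Random functional flags consistent with the secretome class model.

    Each gene is secreted with probability ``secreted_fraction``; secreted
    genes carry a CAZy family with probability ``cazyme_fraction`` or a
    lipase/protease flag with probability ``lipase_protease_fraction``
    (mutually exclusive).  The SSP class then emerges from the secretion flag
    and the protein length, exactly as on real annotations.
    """
    from mycopan.annotation_io import FunctionalAnnotation

    rng = cfg.rng("function")
    families = ["GH5", "GH7", "GT20", "GH37", "AA9", "CE4"]
    out: dict[str, dict[str, FunctionalAnnotation]] = {}
    for sp in sorted(lengths_by_species):
        out[sp] = {}
        for gid in sorted(lengths_by_species[sp]):
            secreted = bool(rng.random() < secreted_fraction)
            cazy = None
            lipo = False
            if secreted:
                u = rng.random()
                if u < cazyme_fraction:
                    cazy = str(rng.choice(families))
                elif u < cazyme_fraction + lipase_protease_fraction:
                    lipo = True
            out[sp][gid] = FunctionalAnnotation(
                gene_id=gid,
                is_secreted=secreted,
                cazy_family=cazy,
                is_lipase_or_protease=lipo,
                kog_category=None,
            )
    return out


def simulate_counts(
    cfg: SimulationConfig, partition_labels: pd.Series | dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with fold changes planted by partition.

    Parameters
    ----------
    partition_labels:
        Mapping gene_id -> pangenome partition; genes inherit their chance of
        being differentially expressed from ``de_fraction_by_partition``.

    Returns
    -------
    counts:
        genes x samples integer DataFrame.
    samples:
        DataFrame (sample_id, condition, replicate) with conditions ECM/FLM.
    truth:
        DataFrame (gene_id, partition, is_de, true_lfc); ``true_lfc`` is the
        planted log2 fold change of ECM over FLM (0 for non-DE genes).
    """
    labels = pd.Series(partition_labels, name="partition")
    rng = cfg.rng("counts")
    genes = list(labels.index)
    n_genes = len(genes)

    log_lo, log_hi = np.log(cfg.nb_mean_range[0]), np.log(cfg.nb_mean_range[1])
    base_mean = np.exp(rng.uniform(log_lo, log_hi, size=n_genes))
    de_prob = labels.map(cfg.de_fraction_by_partition).fillna(0.0).to_numpy(float)
    is_de = rng.random(n_genes) < de_prob
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    true_lfc = np.where(is_de, sign * cfg.lfc_magnitude, 0.0)
    if cfg.lfc_magnitude == 0.0:
        is_de = np.zeros(n_genes, dtype=bool)
        true_lfc = np.zeros(n_genes)

    samples = pd.DataFrame(
        [
            (f"{cond}_{r + 1}", cond, r + 1)
            for cond in ("ECM", "FLM")
            for r in range(cfg.n_replicates)
        ],
        columns=["sample_id", "condition", "replicate"],
    )

    alpha = cfg.nb_dispersion
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, row in samples.iterrows():
        mu = base_mean * np.where(row.condition == "ECM", 2.0**true_lfc, 1.0)
        if alpha <= 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples.sample_id)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "partition": labels.to_numpy(),
            "is_de": is_de,
            "true_lfc": true_lfc,
        }
    )
    return counts_df, samples, truth


def simulate_isotopes(
    n: int,
    true_fraction: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    delta_leaf: float = 200.0,
    delta_flm: float = -28.0,
) -> pd.DataFrame:
    """delta-13C triplets under a two-pool mixing model.

    ``delta_ERM = delta_FLM + f * (delta_leaf - delta_FLM) + noise`` with
    Gaussian noise of standard deviation ``noise_sd`` (permil).  Returns a
    DataFrame (replicate, delta_leaf, delta_erm, delta_flm, true_fraction).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([_STREAM["isotopes"], seed])
    )
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    erm = delta_flm + true_fraction * (delta_leaf - delta_flm) + noise
    return pd.DataFrame(
        {
            "replicate": [f"rep{i + 1}" for i in range(n)],
            "delta_leaf": delta_leaf,
            "delta_erm": erm,
            "delta_flm": delta_flm,
            "true_fraction": true_fraction,
        }
    )
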