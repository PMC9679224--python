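"""Synthetic genomes, annotations, growth curves and evolved proteins with
known ground truth.

The generator emulates the study system qualitatively -- four cold-adapted
yeast species with distinct GC content, amino-acid composition (controllable
very-flexible enrichment), redundant gene families, planted smORFs of every
positional class, temperature-dependent growth kinetics, and protein
families evolved along a known tree -- at desk scale (contigs of ~100 kb
rather than tens of Mb) so every downstream stage can be tested against
recorded truth without any download.

Layout guarantees.  Planted features are laid out sequentially with wide
margins (>= 1.3 kb between any smORF and any unrelated CDS boundary), so a
planted smORF's positional class is unambiguous: CDS-internal smORFs are
embedded in a shifted reading frame of a host CDS (resampling until the
host frame stays stop-free), 5'/3' smORFs sit wholly inside the 1 kb window
on the correct side of their anchor CDS given its strand, and intergenic
smORFs keep > 1 kb clear of every CDS.  Every planted element appears in
exactly one truth-table row; the random background may still contain
incidental ORFs, so truth-based tests assert recall of planted elements,
not precision against the background.

Growth curves.  A600 series follow an exponential phase at exactly the
planted rate, saturating at a per-species carrying capacity K:
``A(t) = min(A0 * exp(r(T) * t), K)`` with A0 = 0.1, daily readings,
Gaussian absorbance noise, clipped at zero.  The rate r(T) is a concave
quadratic peaking at the species' optimum and reaching zero at the
viability bounds.  Planting the rate as the realised exponential-phase
slope (rather than as a logistic shape parameter) is deliberate: growth
rates in this pipeline are *defined* as that slope, so recovery tests
compare like with like.

All emissions are deterministic functions of (spec, seed): per-species
streams are spawned from a single seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .sequence_io import (
    CODON_TO_AA,
    CdsRecord,
    GenomeAssembly,
    STOP_CODONS,
    cds_to_gff3,
    reverse_complement,
    translate,
)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
# SwissProt-like background amino-acid frequencies
_BASE_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}
VF_SET = frozenset("EGKNQS")

_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)

DEFAULT_SPECIES = ("G_gilvescens", "G_martinii", "N_antarctica", "P_glacialis")
DEFAULT_PATHWAYS = (
    "amino acid metabolism",
    "carbohydrate metabolism",
    "cell growth and death",
    "ribosome",
    "signal transduction",
    "transport and catabolism",
)

SMORF_MARGIN = 1400   # background gap flanking each CDS slot
IGAP = 1200           # margin around an intergenic smORF slot


@dataclass(frozen=True)
class GrowthSpec:
    """Per-species growth-curve settings."""

    otg_true: float
    r_peak: float
    t_min: float = 0.0
    t_max: float = 27.0
    temps: tuple[float, ...] = (4.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    noise_sd: float = 0.01
    replicates: int = 3
    days: int = 10


@dataclass(frozen=True)
class TreeSpec:
    """Settings for evolving protein families along a random tree."""

    n_taxa: int = 8
    branch_length_range: tuple[float, float] = (0.02, 0.3)
    rate: float = 1.0


def _default_growth() -> dict[str, GrowthSpec]:
    # mirrors the study strains: OTG 10-20 degC, peak Gr 0.07-0.18 per day
    return {
        "G_gilvescens": GrowthSpec(otg_true=20.0, r_peak=0.1579, t_max=27.0),
        "G_martinii": GrowthSpec(otg_true=10.0, r_peak=0.0726, t_max=17.0),
        "N_antarctica": GrowthSpec(otg_true=15.0, r_peak=0.0736, t_max=17.0),
        "P_glacialis": GrowthSpec(otg_true=15.0, r_peak=0.175, t_max=27.0),
    }


@dataclass
class SyntheticSpec:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    species: tuple[str, ...] = DEFAULT_SPECIES
    contigs_per_species: int = 3
    contig_length_bp: int = 100_000
    gc_target: float = 0.55
    n_cds: int = 30
    cds_length_range: tuple[int, int] = (70, 180)  # codons incl. start/stop
    vf_effect: dict[str, float] = field(
        default_factory=lambda: {
            "G_gilvescens": 0.0, "G_martinii": 4.0,
            "N_antarctica": 0.0, "P_glacialis": 4.0,
        }
    )
    planted_smorfs: tuple[tuple[str, int], ...] = (
        ("CDSSmORF", 5), ("5'SmORF", 5), ("3'SmORF", 5), ("intergenic", 5),
    )
    redundant_families: tuple[tuple[str, int], ...] = (
        ("P-loop containing nucleoside triphosphate hydrolase", 7),
        ("alpha/beta hydrolase", 5),
        ("major facilitator superfamily protein", 4),
    )
    unannotated_fraction: float = 0.1
    pathways: tuple[str, ...] = DEFAULT_PATHWAYS
    k_range: tuple[float, float] = (1.0, 1.5)
    growth: dict[str, GrowthSpec] = field(default_factory=_default_growth)
    tree_spec: TreeSpec = field(default_factory=TreeSpec)

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.n_cds <= 0 or self.contigs_per_species <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.cds_length_range
        if lo < 10 or hi < lo:
            raise ValueError("cds_length_range must be sane (>=10 codons)")

    def rng_for(self, species: str, stream: int) -> np.random.Generator:
        idx = self.species.index(species)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx, stream))
        return np.random.default_rng(ss)


def _aa_probs(vf_shift_points: float) -> tuple[list[str], np.ndarray]:
    """Background composition with the Vf share shifted by N percentage points."""
    aas = list(AA_ORDER)
    p = np.array([_BASE_FREQ[a] for a in aas])
    p = p / p.sum()
    base_vf = sum(p[i] for i, a in enumerate(aas) if a in VF_SET)
    target = base_vf + vf_shift_points / 100.0
    if not 0.0 < target < 1.0:
        raise ValueError("vf shift drives class probability out of (0,1)")
    for i, a in enumerate(aas):
        p[i] *= target / base_vf if a in VF_SET else (1 - target) / (1 - base_vf)
    return aas, p / p.sum()


def _sense_codons(rng: np.random.Generator, aas: list[str], p: np.ndarray, n: int) -> list[str]:
    residues = rng.choice(aas, size=n, p=p)
    return [_CODONS_FOR[aa][rng.integers(0, len(_CODONS_FOR[aa]))] for aa in residues]


def _smorf_nt(rng: np.random.Generator, aas: list[str], p: np.ndarray, codons_total: int) -> str:
    body = _sense_codons(rng, aas, p, codons_total - 2)
    stop = sorted(STOP_CODONS)[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _frame_of(start: int, end: int, strand: str, contig_len: int) -> int:
    if strand == "+":
        return (start - 1) % 3
    return (contig_len - end) % 3


def generate_genome(
    spec: SyntheticSpec, species: str
) -> tuple[GenomeAssembly, str, dict[str, pd.DataFrame]]:
    """Emit one species' assembly, its GFF3 annotation, and truth tables.

    Returns ``(assembly, gff3_text, truth)`` where ``truth`` holds the
    DataFrames ``cds`` (one row per planted CDS, with its final peptide),
    ``smorfs`` (one row per planted smORF with coordinates, strand, frame
    and class) and ``families`` (label, planted copy count).
    Deterministic: the same (spec, species) yields byte-identical output.
    """
    rng = spec.rng_for(species, stream=0)
    aas, p_aa = _aa_probs(spec.vf_effect.get(species, 0.0))
    gc = spec.gc_target
    L = spec.contig_length_bp
    n_contigs = spec.contigs_per_species

    # ---- feature plan -------------------------------------------------
    family_labels: list[str] = []
    for label, copies in spec.redundant_families:
        family_labels.extend([label] * copies)
    if len(family_labels) > spec.n_cds:
        raise ValueError("redundant family copies exceed n_cds")
    n_rest = spec.n_cds - len(family_labels)
    n_unann = int(round(spec.unannotated_fraction * n_rest))
    labels = family_labels + [
        f"putative protein {i:03d}" for i in range(n_rest - n_unann)
    ] + [""] * n_unann

    smorf_counts = dict(spec.planted_smorfs)
    n_embed = smorf_counts.get("CDSSmORF", 0)
    n_five = smorf_counts.get("5'SmORF", 0)
    n_three = smorf_counts.get("3'SmORF", 0)
    n_inter = smorf_counts.get("intergenic", 0)
    if max(n_embed, n_five, n_three) > spec.n_cds:
        raise ValueError("more planted smORFs than CDS slots")

    # ---- background ---------------------------------------------------
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = [
        rng.choice(bases, size=L, p=probs) for _ in range(n_contigs)
    ]
    cursors = [0] * n_contigs

    cds_rows: list[dict] = []
    smorf_rows: list[dict] = []

    def place(contig_idx: int, length: int) -> int:
        """Reserve `length` bp on a contig, returning the 0-based offset."""
        off = cursors[contig_idx]
        if off + length > L:
            raise ValueError(
                f"infeasible packing: contig {contig_idx} of {species} "
                f"cannot hold the requested features"
            )
        cursors[contig_idx] = off + length
        return off

    def write(contig_idx: int, off: int, nt: str) -> None:
        contigs[contig_idx][off : off + len(nt)] = list(nt)

    # ---- CDS slots ----------------------------------------------------
    lo, hi = spec.cds_length_range
    for i, label in enumerate(labels):
        contig_idx = i % n_contigs
        embed = i < n_embed
        want_five = i < n_five
        want_three = i < n_three
        strand = "+" if embed else ("+", "-")[rng.integers(0, 2)]
        c = int(rng.integers(lo, hi + 1))
        nt_len = 3 * c

        codons = ["ATG"] + _sense_codons(rng, aas, p_aa, c - 2)
        codons.append(sorted(STOP_CODONS)[rng.integers(0, 3)])
        cds_nt = "".join(codons)

        embedded = None
        if embed:
            m = int(rng.integers(10, min(60, c - 4) + 1))
            span = 3 * m
            offsets = [o for o in range(4, nt_len - 3 - span + 1) if o % 3 == 1]
            o = int(offsets[rng.integers(0, len(offsets))])
            for _attempt in range(200):
                sm_nt = _smorf_nt(rng, aas, p_aa, m)
                trial = cds_nt[:o] + sm_nt + cds_nt[o + span :]
                inner = [trial[k : k + 3] for k in range(3, nt_len - 3, 3)]
                if not any(cd in STOP_CODONS for cd in inner):
                    cds_nt = trial
                    embedded = (o, span, sm_nt)
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not embed smORF without host stops")

        pre = SMORF_MARGIN + int(rng.integers(0, 200))
        post = SMORF_MARGIN + int(rng.integers(0, 200))
        off = place(contig_idx, pre + nt_len + post)
        cds_off = off + pre  # 0-based
        start, end = cds_off + 1, cds_off + nt_len
        write(contig_idx, cds_off, cds_nt if strand == "+" else reverse_complement(cds_nt))

        peptide = translate(cds_nt).rstrip("*")
        pathways: tuple[str, ...] = ()
        if label:
            k = int(rng.integers(1, 3))
            pathways = tuple(
                sorted(rng.choice(spec.pathways, size=k, replace=False))
            )
        cds_rows.append(
            {
                "species": species,
                "cds_id": f"{species}_cds_{i:04d}",
                "contig_id": f"{species}_contig_{contig_idx + 1}",
                "start": start,
                "end": end,
                "strand": strand,
                "annotation_label": label,
                "pathways": ";".join(pathways),
                "peptide": peptide,
            }
        )

        if embedded is not None:
            o, span, sm_nt = embedded
            s0 = cds_off + o
            smorf_rows.append(
                {
                    "species": species,
                    "contig_id": f"{species}_contig_{contig_idx + 1}",
                    "start": s0 + 1,
                    "end": s0 + span,
                    "strand": "+",
                    "frame": s0 % 3,
                    "nt_seq": sm_nt,
                    "peptide": translate(sm_nt).rstrip("*"),
                    "position_class": "CDSSmORF",
                }
            )

        for want, side_class in ((want_five, "5'SmORF"), (want_three, "3'SmORF")):
            if not want:
                continue
            # window on the correct side of the CDS given its strand
            left = (side_class == "5'SmORF") == (strand == "+")
            m = int(rng.integers(10, 41))
            span = 3 * m
            nt = _smorf_nt(rng, aas, p_aa, m)
            if left:
                w_lo, w_hi = start - 1000, start - 1
            else:
                w_lo, w_hi = end + 1, end + 1000
            s = int(rng.integers(w_lo, w_hi - span + 2))  # 1-based start
            orf_strand = ("+", "-")[rng.integers(0, 2)]
            write(
                contig_idx,
                s - 1,
                nt if orf_strand == "+" else reverse_complement(nt),
            )
            smorf_rows.append(
                {
                    "species": species,
                    "contig_id": f"{species}_contig_{contig_idx + 1}",
                    "start": s,
                    "end": s + span - 1,
                    "strand": orf_strand,
                    "frame": _frame_of(s, s + span - 1, orf_strand, L),
                    "nt_seq": nt,
                    "peptide": translate(nt).rstrip("*"),
                    "position_class": side_class,
                }
            )

    # ---- intergenic smORF slots --------------------------------------
    for i in range(n_inter):
        contig_idx = i % n_contigs
        m = int(rng.integers(10, 41))
        span = 3 * m
        nt = _smorf_nt(rng, aas, p_aa, m)
        off = place(contig_idx, IGAP + span + IGAP)
        s = off + IGAP + 1
        orf_strand = ("+", "-")[rng.integers(0, 2)]
        write(contig_idx, s - 1, nt if orf_strand == "+" else reverse_complement(nt))
        smorf_rows.append(
            {
                "species": species,
                "contig_id": f"{species}_contig_{contig_idx + 1}",
                "start": s,
                "end": s + span - 1,
                "strand": orf_strand,
                "frame": _frame_of(s, s + span - 1, orf_strand, L),
                "nt_seq": nt,
                "peptide": translate(nt).rstrip("*"),
                "position_class": "intergenic",
            }
        )

    assembly = GenomeAssembly(
        name=species,
        contigs=[
            (f"{species}_contig_{k + 1}", "".join(contigs[k]))
            for k in range(n_contigs)
        ],
    )
    records = [
        CdsRecord(
            cds_id=row["cds_id"],
            contig_id=row["contig_id"],
            start=row["start"],
            end=row["end"],
            strand=row["strand"],
            peptide=row["peptide"],
            annotation_label=row["annotation_label"],
            pathway_labels=frozenset(
                x for x in row["pathways"].split(";") if x
            ),
        )
        for row in cds_rows
    ]
    gff3 = cds_to_gff3(records, source="coldadapt-synth")
    truth = {
        "cds": pd.DataFrame(cds_rows),
        "smorfs": pd.DataFrame(smorf_rows),
        "families": pd.DataFrame(
            [{"annotation_label": l, "copies": c} for l, c in spec.redundant_families]
        ),
    }
    return assembly, gff3, truth


def growth_rate_at(gspec: GrowthSpec, temperature: float) -> float:
    """Planted exponential rate at a temperature: concave quadratic in T,
    peaking at the optimum and zero outside the viability range."""
    T, otg = temperature, gspec.otg_true
    if T < gspec.t_min or T > gspec.t_max:
        return 0.0
    width = (otg - gspec.t_min) if T <= otg else (gspec.t_max - otg)
    if width <= 0:
        return gspec.r_peak if T == otg else 0.0
    return float(gspec.r_peak * max(0.0, 1.0 - ((T - otg) / width) ** 2))


def generate_growth_curves(
    spec: SyntheticSpec, species: str
) -> tuple[list[GrowthCurve], dict]:
    """Simulate replicate A600 series over the temperature panel.

    Returns the curves plus a truth dict with the planted per-temperature
    rates, the carrying capacity and the true optimum temperature.
    """
    gspec = spec.growth[species]
    rng = spec.rng_for(species, stream=1)
    K = float(rng.uniform(*spec.k_range))
    times = np.arange(0.0, gspec.days + 1.0)
    a0 = 0.1
    curves: list[GrowthCurve] = []
    r_by_temp: dict[float, float] = {}
    for T in gspec.temps:
        r = growth_rate_at(gspec, T)
        r_by_temp[T] = r
        clean = np.minimum(a0 * np.exp(r * times), K)
        for rep in range(gspec.replicates):
            noisy = clean + rng.normal(0.0, gspec.noise_sd, times.size)
            curves.append(
                GrowthCurve(
                    strain=species,
                    temperature=T,
                    replicate=rep + 1,
                    times=times.copy(),
                    a600=np.clip(noisy, 0.0, None),
                )
            )
    truth = {"otg_true": gspec.otg_true, "K": K, "r_by_temp": r_by_temp}
    return curves, truth


def evolve_proteins(
    tree_spec: TreeSpec, root_peptide: str, seed: int = 0
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Evolve a root peptide along a random tree; returns (truth tree, leaves).

    Topology is built by random successive joins; branch lengths are
    uniform in the configured range.  Substitutions per branch are Poisson
    with mean rate x length x sites, each replacing a uniformly chosen site
    with a uniformly chosen alternative residue.  No indels.
    """
    if len(root_peptide) < 50:
        raise ValueError("root peptide must be at least 50 residues")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(tree_spec.n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    subtrees = []
    lo, hi = tree_spec.branch_length_range
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        subtrees.append(node)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        parent = dendropy.Node()
        for child in (subtrees[i], subtrees[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(lo, hi))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(parent)
    tree.seed_node = subtrees[0]

    alphabet = np.array(list(AA_ORDER))
    leaves: dict[str, str] = {}

    def walk(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            child_seq = seq.copy()
            nsub = rng.poisson(tree_spec.rate * child.edge.length * seq.size)
            for _ in range(nsub):
                pos = int(rng.integers(0, seq.size))
                current = child_seq[pos]
                choices = alphabet[alphabet != current]
                child_seq[pos] = choices[rng.integers(0, choices.size)]
            if child.is_leaf():
                leaves[child.taxon.label] = "".join(child_seq)
            else:
                walk(child, child_seq)

    walk(tree.seed_node, np.array(list(root_peptide)))
    return tree, leaves
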