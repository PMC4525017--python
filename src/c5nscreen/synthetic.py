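"""Synthetic data with known ground truth for the whole screening pipeline.

Everything the pipeline consumes can be generated here: hemA-like coding
sequences of controlled class (cyclizing vs classical vs off-target vs
negative), annotated contigs carrying the C5N gene triad in each canonical
arrangement, whole screening cohorts, labelled phylogenetic reference
panels, and grouped densitometric fingerprint profiles.

The gene generator emulates the statistical structure the analysis
assumes rather than real hemA biology:

* streptomycete-style coding sequences with a strong, controllable GC bias
  at the third codon position (GC3), built on a fixed 400-residue scaffold
  shared with the packaged classifier reference;
* the two conserved primer motifs embedded as literal annealing sites at
  canonical spacing, so the degenerate screening primers produce the
  519 bp band;
* diagnostic codons (83/149/231/365) forced to the class-appropriate
  residue states;
* branch identity realised as a deterministic set of synonymous "barcode"
  codons inside the amplified region, so fragments cluster by branch
  without perturbing the protein;
* off-target templates (8-amino-7-oxononanoate synthase stand-ins) with
  both primer sites but a shorter spacer, yielding the "slightly smaller"
  band;
* negatives with neither motif.

Determinism: every generator derives its randomness from the config seed
(or an explicit seed argument), so identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codons import AA_TO_CODONS, revcomp, translate_nt
from .classifier import load_default_panel
from .cluster import GeneFeature
from .fingerprint import FingerprintProfile
from .phylo import PanelEntry, ReferencePanel

__all__ = [
    "SynthesisConfig",
    "TruthRecord",
    "GeneRecord",
    "ContigRecord",
    "CLASS_LABELS",
    "BRANCHES_BY_CLASS",
    "synth_alas_gene",
    "synth_cohort",
    "synth_cluster_contig",
    "synth_fingerprints",
    "synth_reference_panel",
    "synth_gc_steered_fragment",
    "amplicon_region",
    "write_cohort_fasta",
    "write_truth_tsv",
    "write_fingerprints_csv",
]

# ---------------------------------------------------------------------------
# frozen layout of the synthetic gene (shared with the packaged reference)

GENE_CODONS = 400
#: nt coordinates (0-based, half-open) of the canonical amplified region
AMPLICON_SLICE = slice(207, 726)

# codons 70..78: a concrete expansion of the forward primer plus a CC pad;
# codons 234..242: the reverse-complemented concrete expansion of the
# reverse primer.  The canonical product spans nt 207..726 = 519 bp.
_FWD_SITE = "GTCTGGTGCTCGGCAACGACTACCT" + "CC"
_REV_SITE = "AGCGAGGTCCACGCCGTCGGCATGTAC"
_FWD_CODON0, _REV_CODON0 = 69, 233

_DIAG = {  # 1-based scaffold position -> (classical residue, cALAS residues)
    83: ("T", ("S",)),
    149: ("I", ("L", "V")),
    231: ("D", ("T",)),
    365: ("T", ("S",)),
}

CLASS_LABELS = (
    "cALAS_purple",
    "cALAS_green",
    "cALAS_other",
    "classical_highGC",
    "classical_lowGC",
    "AONS_offtarget",
    "negative",
)
_CLASS_CODE = {c: i for i, c in enumerate(CLASS_LABELS)}

BRANCHES_BY_CLASS = {
    "cALAS_purple": ("manumycin", "colabomycin", "annimycin_ECO", "reductiomycin"),
    "cALAS_green": ("moenomycin_I", "moenomycin_II_L155175", "bafilomycin"),
    "cALAS_other": ("orange", "brown"),
}
BLUE_BRANCHES = ("blue_I", "blue_II")
ALL_BRANCHES = sum(BRANCHES_BY_CLASS.values(), ()) + BLUE_BRANCHES

_ARRANGEMENT_BY_CLASS = {
    "cALAS_purple": "head_to_tail",
    "cALAS_green": "divergent",
    "cALAS_other": "head_to_tail",
}

# streptomycete-like amino acid frequencies used for scaffold-free proteins
_AAS = tuple("ARNDCQEGHILKMFPSTWYV")
_AA_FREQ = np.array(
    [0.127, 0.087, 0.019, 0.059, 0.008, 0.026, 0.059, 0.094, 0.022, 0.034,
     0.100, 0.024, 0.017, 0.027, 0.069, 0.056, 0.064, 0.015, 0.022, 0.084]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

# linear calibration of the GC-steered fragment generator: fragment GC
# fraction ~= intercept + slope * u, u in [0,1] driving both GC3 and the
# codon-internal GC preference
_GC_STEER_INTERCEPT, _GC_STEER_SLOPE = 0.416, 0.306

_DEFAULT_MIX = {
    "cALAS_purple": 0.05,
    "cALAS_green": 0.04,
    "cALAS_other": 0.02,
    "classical_highGC": 0.01,
    "classical_lowGC": 0.01,
    "AONS_offtarget": 0.02,
    "negative": 0.85,
}


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the gene/cohort generator.

    canonical_spacing is the internal distance in nt between the two
    primer footprints; its default (519 - 25 - 27 = 467) makes the full
    product match the canonical 519 bp band.  class_mix gives the cohort
    composition and must sum to 1.
    """

    seed: int = 0
    gc3_target: float = 0.90
    gc3_low_target: float = 0.45
    mutation_rate: float = 0.0
    canonical_spacing: int = 467
    offtarget_delta: int = 60
    spacing_jitter: int = 0
    codon_prefer: str = "auto"
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc3_target <= 1.0 or not 0.0 <= self.gc3_low_target <= 1.0:
            raise ValueError("gc3 targets must be fractions in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise ValueError("mutation_rate must be in [0, 0.3]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        unknown = set(self.class_mix) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in mix: {sorted(unknown)}")
        if not 30 <= self.offtarget_delta <= 90:
            raise ValueError("offtarget_delta must be within [30, 90] nt")


@dataclass(frozen=True)
class TruthRecord:
    strain_id: str
    true_class: str
    true_branch: str | None = None
    true_arrangement: str | None = None
    true_group: str | None = None

    def __post_init__(self) -> None:
        if self.true_class not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.true_class!r}")
        if (self.true_branch is not None) != self.true_class.startswith("cALAS"):
            raise ValueError("true_branch must be present iff the class is a cALAS class")


@dataclass(frozen=True)
class GeneRecord:
    strain_id: str
    cds: str
    protein: str
    truth: TruthRecord


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    sequence: str
    features: tuple[GeneFeature, ...]
    truth: TruthRecord
    hemA: GeneRecord


# ---------------------------------------------------------------------------
# codon machinery

def _scaffold() -> str:
    return load_default_panel().reference_protein


def _prefer_for(q: float) -> str:
    return "max" if q >= 0.7 else ("min" if q <= 0.45 else "uniform")


def _pick_codon(aa: str, q: float, prefer: str, rng: np.random.Generator) -> str:
    codons = AA_TO_CODONS[aa]
    s = [c for c in codons if c[2] in "GC"]
    w = [c for c in codons if c[2] not in "GC"]
    pool = s if (s and (not w or rng.random() < q)) else w
    if prefer in ("max", "min") and len(pool) > 1:
        pick = max if prefer == "max" else min
        best = pick(sum(b in "GC" for b in c[:2]) for c in pool)
        pool = [c for c in pool if sum(b in "GC" for b in c[:2]) == best]
    return pool[rng.integers(len(pool))]


def _branch_barcode_positions(scaffold: str) -> tuple[int, ...]:
    """Sixty codon indices (0-based) inside the amplified spacer reserved for
    branch-identity codons; fixed once for the package."""
    rng = np.random.default_rng(777)
    candidates = [
        i for i in range(84, 230)
        if len(AA_TO_CODONS[scaffold[i]]) >= 2 and (i + 1) not in _DIAG
    ]
    return tuple(sorted(rng.choice(candidates, size=60, replace=False).tolist()))


def _branch_codons(branch: str, scaffold: str) -> dict[int, str]:
    """Deterministic codon choice at the barcode positions for one branch."""
    positions = _branch_barcode_positions(scaffold)
    rng = np.random.default_rng(zlib.crc32(branch.encode()))
    return {i: AA_TO_CODONS[scaffold[i]][rng.integers(len(AA_TO_CODONS[scaffold[i]]))] for i in positions}


def _build_cds(
    aa_seq: Sequence[str],
    fixed: Mapping[int, str],
    gc3_target: float,
    prefer: str,
    rng: np.random.Generator,
) -> list[str]:
    """Sample codons for *aa_seq* honouring *fixed* codons and hitting
    *gc3_target* in expectation (the flexible-codon GC3 probability is
    solved so the gene-wide mean lands on target)."""
    n = len(aa_seq)
    forced = [i for i in range(n) if i not in fixed and len(AA_TO_CODONS[aa_seq[i]]) == 1]
    fixed_gc3 = sum(c[2] in "GC" for c in fixed.values())
    forced_gc3 = sum(AA_TO_CODONS[aa_seq[i]][0][2] in "GC" for i in forced)
    n_flex = n - len(fixed) - len(forced)
    q = gc3_target if n_flex == 0 else (gc3_target * n - fixed_gc3 - forced_gc3) / n_flex
    q = float(min(max(q, 0.0), 1.0))
    out = []
    for i in range(n):
        if i in fixed:
            out.append(fixed[i])
        elif len(AA_TO_CODONS[aa_seq[i]]) == 1:
            out.append(AA_TO_CODONS[aa_seq[i]][0])
        else:
            out.append(_pick_codon(aa_seq[i], q, prefer, rng))
    return out


def _mutate(cds: str, rate: float, protected: list[tuple[int, int]], rng: np.random.Generator) -> str:
    if rate <= 0:
        return cds
    arr = np.frombuffer(cds.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    for lo, hi in protected:
        mask[lo:hi] = False
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in np.nonzero(mask)[0]:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def amplicon_region(cds: str) -> str:
    """The canonical 519 nt amplified region of a generator CDS built at
    default spacing."""
    return cds[AMPLICON_SLICE]


# ---------------------------------------------------------------------------
# gene generator

def synth_alas_gene(
    class_label: str,
    cfg: SynthesisConfig,
    strain_id: str = "SYN0001",
    branch: str | None = None,
    index: int = 0,
) -> GeneRecord:
    """Generate one nucleotide CDS (+ translation + truth record).

    Amplifiable classes carry a forward-primer site and a reverse-primer
    site separated by ``cfg.canonical_spacing`` nt; diagnostic codons
    encode the class-appropriate residues; GC3 tracks the config target.
    The negative class contains neither motif.  Primer footprints and
    diagnostic codons are never mutated, so truth labels stay valid at any
    mutation rate.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng([abs(int(cfg.seed)), _CLASS_CODE[class_label], int(index)])
    scaffold = _scaffold()

    is_calas = class_label.startswith("cALAS")
    if is_calas:
        if branch is None:
            options = BRANCHES_BY_CLASS[class_label]
            branch = options[rng.integers(len(options))]
    elif branch is not None and branch not in BLUE_BRANCHES:
        raise ValueError("non-cALAS classes only accept blue-branch barcodes")
    truth = TruthRecord(
        strain_id,
        class_label,
        true_branch=branch if is_calas else None,
        true_arrangement=_ARRANGEMENT_BY_CLASS.get(class_label),
    )

    gc3 = cfg.gc3_low_target if class_label == "classical_lowGC" else cfg.gc3_target
    prefer = _prefer_for(gc3) if cfg.codon_prefer == "auto" else cfg.codon_prefer

    if class_label == "negative":
        aa_seq = [str(a) for a in rng.choice(_AAS, size=GENE_CODONS, p=_AA_FREQ)]
        codons = _build_cds(aa_seq, {}, gc3, prefer, rng)
        cds = _mutate("".join(codons) + "TGA", cfg.mutation_rate, [], rng)
        return GeneRecord(strain_id, cds, translate_nt(cds)[:-1], truth)

    aa_seq = list(scaffold)
    for pos, (classical, calas) in _DIAG.items():
        if is_calas:
            aa_seq[pos - 1] = calas[rng.integers(len(calas))]
        else:
            aa_seq[pos - 1] = classical

    fixed: dict[int, str] = {}
    for k in range(9):
        fixed[_FWD_CODON0 + k] = _FWD_SITE[3 * k : 3 * k + 3]
        fixed[_REV_CODON0 + k] = _REV_SITE[3 * k : 3 * k + 3]
    if branch is not None:
        fixed.update(_branch_codons(branch, scaffold))

    codons = _build_cds(aa_seq, fixed, gc3, prefer, rng)
    cds = "".join(codons) + "TGA"

    # spacing adjustment: insert/delete inside codons 201..230, i.e. between
    # diagnostic codons 149 and 231, leaving every constrained codon intact
    spacing = cfg.canonical_spacing
    if cfg.spacing_jitter:
        spacing += int(rng.integers(-cfg.spacing_jitter, cfg.spacing_jitter + 1))
    if class_label == "AONS_offtarget":
        spacing -= cfg.offtarget_delta
    delta = spacing - 467
    if not -90 <= delta <= 90:
        raise ValueError("spacing must stay within 90 nt of canonical")
    if delta < 0:
        cds = cds[:600] + cds[600 - delta :]
    elif delta > 0:
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, delta))
        cds = cds[:600] + filler + cds[600:]

    protected = [(207, 232), (699 + delta, 726 + delta)]
    for pos in _DIAG:
        lo = (pos - 1) * 3 + (delta if pos > 200 else 0)
        protected.append((lo, lo + 3))
    cds = _mutate(cds, cfg.mutation_rate, protected, rng)
    protein = translate_nt(cds)
    return GeneRecord(strain_id, cds, protein[: len(protein) - 1], truth)


# ---------------------------------------------------------------------------
# cohorts

def synth_cohort(n: int, cfg: SynthesisConfig) -> list[GeneRecord]:
    """Generate *n* strain records with per-class counts given by the
    largest-remainder rounding of ``cfg.class_mix``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    mix = [(c, cfg.class_mix.get(c, 0.0)) for c in CLASS_LABELS if cfg.class_mix.get(c, 0.0) > 0]
    raw = [(c, f * n) for c, f in mix]
    counts = {c: int(x) for c, x in raw}
    short = n - sum(counts.values())
    for c, _ in sorted(raw, key=lambda t: (-(t[1] - int(t[1])), CLASS_LABELS.index(t[0])))[:short]:
        counts[c] += 1
    labels = [c for c, k in counts.items() for _ in range(k)]
    rng = np.random.default_rng([abs(int(cfg.seed)), 10_007])
    order = rng.permutation(len(labels))
    records = []
    for i, j in enumerate(order):
        records.append(
            synth_alas_gene(labels[j], cfg, strain_id=f"SYN{i + 1:04d}", index=i)
        )
    return records


def synth_cluster_contig(arrangement: str, cfg: SynthesisConfig, contig_id: str | None = None) -> ContigRecord:
    """An annotated contig realising one triad arrangement.

    head_to_tail: ams, hemA, all adjacent on +; divergent: hemA on the
    opposite strand upstream of the ams-all pair; atypical: all three on
    one strand but out of order; incomplete: hemA alone.  The hemA feature
    sequence is a synth_alas_gene product of the matching class.
    """
    layouts = {
        "head_to_tail": [("ams", "+"), ("hemA", "+"), ("all", "+")],
        "divergent": [("hemA", "-"), ("ams", "+"), ("all", "+")],
        "atypical": [("ams", "+"), ("all", "+"), ("hemA", "+")],
        "incomplete": [("hemA", "+")],
    }
    if arrangement not in layouts:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    hem_class = {"divergent": "cALAS_green"}.get(arrangement, "cALAS_purple")
    contig_id = contig_id or f"contig_{arrangement}"
    rng = np.random.default_rng([abs(int(cfg.seed)), 20_011, list(layouts).index(arrangement)])

    hem = synth_alas_gene(hem_class, cfg, strain_id=contig_id, index=0)
    hem = replace(hem, truth=replace(hem.truth, true_arrangement=arrangement))

    def random_gene(n_codons: int) -> str:
        aa = [str(a) for a in rng.choice(_AAS, size=n_codons, p=_AA_FREQ)]
        return "".join(_build_cds(aa, {}, cfg.gc3_target, _prefer_for(cfg.gc3_target), rng)) + "TGA"

    gene_seqs = {"ams": random_gene(300), "all": random_gene(500), "hemA": hem.cds}
    intergenic_p = np.array([0.15, 0.35, 0.35, 0.15])

    def spacer(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=intergenic_p))

    parts = [spacer(int(rng.integers(200, 400)))]
    features: list[GeneFeature] = []
    pos = len(parts[0])
    for label, strand in layouts[arrangement]:
        seq = gene_seqs[label]
        embedded = seq if strand == "+" else revcomp(seq)
        features.append(GeneFeature(f"{contig_id}_{label}", label, contig_id, pos, pos + len(seq), strand))
        parts.append(embedded)
        pos += len(seq)
        gap = spacer(int(rng.integers(80, 300)))
        parts.append(gap)
        pos += len(gap)
    sequence = "".join(parts)
    return ContigRecord(contig_id, sequence, tuple(features), hem.truth, hem)


# ---------------------------------------------------------------------------
# phylogenetic reference panel and GC-steered fragments

def synth_reference_panel(seed: int = 0, entries_per_branch: int = 2) -> ReferencePanel:
    """A labelled panel of aligned amplified-region fragments, >= 2 entries
    per branch, including the classical blue_I / blue_II branches."""
    if entries_per_branch < 2:
        raise ValueError("need >= 2 entries per branch for support estimation")
    entries = []
    for branch in ALL_BRANCHES:
        if branch in BLUE_BRANCHES:
            class_label = "classical_highGC" if branch == "blue_I" else "classical_lowGC"
        else:
            class_label = next(c for c, bs in BRANCHES_BY_CLASS.items() if branch in bs)
        for j in range(entries_per_branch):
            cfg = SynthesisConfig(seed=seed, mutation_rate=0.004)
            rec = synth_alas_gene(
                class_label, cfg, strain_id=f"{branch}_ref{j + 1}", branch=branch,
                index=1000 * ALL_BRANCHES.index(branch) + j,
            )
            entries.append(PanelEntry(rec.strain_id, amplicon_region(rec.cds), branch))
    return ReferencePanel(tuple(entries))


def synth_gc_steered_fragment(gc_percent_target: float, seed: int, class_label: str = "classical_highGC") -> GeneRecord:
    """A non-cALAS gene whose amplified region is steered toward a GC%
    target (calibration is linear in the steering parameter; the realised
    GC is what downstream analysis measures)."""
    u = (gc_percent_target / 100.0 - _GC_STEER_INTERCEPT) / _GC_STEER_SLOPE
    u = float(min(max(u, 0.0), 1.0))
    cfg = SynthesisConfig(seed=seed, gc3_target=u, gc3_low_target=u, codon_prefer="max")
    rng_index = int(round(gc_percent_target * 100))
    return synth_alas_gene(class_label, cfg, strain_id=f"GC{gc_percent_target:.1f}", index=rng_index)


# ---------------------------------------------------------------------------
# fingerprints

def synth_fingerprints(
    n_groups: int,
    members: int,
    noise_sd: float,
    seed: int = 0,
    length: int = 256,
    n_habitats: int = 3,
) -> tuple[list[FingerprintProfile], dict[str, str]]:
    """Grouped densitometric lane profiles: one smooth template curve per
    group, members are the template plus i.i.d. Gaussian noise of scale
    *noise_sd* (clipped at zero).  Returns (profiles, truth_groups)."""
    if n_groups < 1 or members < 1:
        raise ValueError("n_groups and members must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if length < 64:
        raise ValueError("curves must have at least 64 samples")
    rng = np.random.default_rng([abs(int(seed)), 30_013])
    x = np.arange(length)
    profiles: list[FingerprintProfile] = []
    truth: dict[str, str] = {}
    for g in range(n_groups):
        n_peaks = int(rng.integers(8, 16))
        centers = rng.uniform(0, length, n_peaks)
        widths = rng.uniform(2.0, 8.0, n_peaks)
        heights = rng.uniform(0.3, 1.0, n_peaks)
        template = 0.1 + sum(
            h * np.exp(-0.5 * ((x - c) / w) ** 2) for c, w, h in zip(centers, widths, heights)
        )
        for m in range(members):
            curve = np.clip(template + rng.normal(0.0, noise_sd, length), 0.0, None)
            sid = f"FP_G{g + 1:02d}_M{m + 1:02d}"
            habitat = f"habitat{int(rng.integers(n_habitats)) + 1}"
            profiles.append(FingerprintProfile(sid, habitat, curve))
            truth[sid] = f"G{g + 1:02d}"
    return profiles, truth


# ---------------------------------------------------------------------------
# writers

def write_cohort_fasta(records: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.strain_id}\n{r.cds}\n")


def write_truth_tsv(records: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\ttrue_class\ttrue_branch\ttrue_arrangement\ttrue_group\n")
        for r in records:
            t = r.truth
            fh.write(
                f"{t.strain_id}\t{t.true_class}\t{t.true_branch or '.'}\t"
                f"{t.true_arrangement or '.'}\t{t.true_group or '.'}\n"
            )


def write_fingerprints_csv(profiles: Sequence[FingerprintProfile], path) -> None:
    """CSV with one lane per column, header = strain ids."""
    with open(path, "w") as fh:
        fh.write(",".join(p.strain_id for p in profiles) + "\n")
        n = len(profiles[0].curve)
        for i in range(n):
            fh.write(",".join(f"{p.curve[i]:.6g}" for p in profiles) + "\n")
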