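"""Synthetic transcript sets and expression tables with planted ground truth.

Every downstream stage of the pipeline (redundancy collapse, ORF/SSR/lncRNA
scanning, alternative-splicing calling, differential expression, co-expression
networks) is exercisable against data generated here, with the planted features
recorded in a :class:`TruthSet` so recovery can be scored exactly.

The generator emulates the data regime of a PacBio full-length rhizome
transcriptome quantified by short-read counts over five tissues with three
replicates each:

* multi-isoform gene pairs sharing identical 5'/3' flanking blocks with an
  internal insertion present only in the long isoform (alternative splicing),
* near-duplicate transcript copies differing by point substitutions only,
* coding transcripts carrying a planted ORF with biased codon usage, and
  noncoding transcripts whose nucleotides are permuted to destroy any codon
  or hexamer structure,
* planted mono-/di-/tri-nucleotide microsatellites,
* a negative-binomial count matrix with block-correlated "TF modules" driven
  by tissue-level latent factors, one of which drives a physiological trait.

All randomness flows from ``SynthConfig.seed``; the same seed reproduces every
output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

NUCS = np.array(list("ACGT"))

#: Sense-codon usage weights for planted coding regions.  Deliberately
#: non-uniform (roughly plant-like GC3 preferences) so that in-frame hexamer
#: statistics of coding sequence separate cleanly from permuted background.
_CODON_WEIGHTS = {
    "GCT": 28, "GCC": 12, "GCA": 18, "GCG": 6,
    "TGT": 5, "TGC": 4,
    "GAT": 32, "GAC": 12,
    "GAA": 30, "GAG": 18,
    "TTT": 18, "TTC": 14,
    "GGT": 22, "GGC": 8, "GGA": 20, "GGG": 6,
    "CAT": 12, "CAC": 6,
    "ATT": 22, "ATC": 12, "ATA": 8,
    "AAA": 28, "AAG": 22,
    "TTA": 8, "TTG": 14, "CTT": 18, "CTC": 10, "CTA": 6, "CTG": 8,
    "ATG": 16,
    "AAT": 22, "AAC": 14,
    "CCT": 14, "CCC": 4, "CCA": 14, "CCG": 4,
    "CAA": 18, "CAG": 10,
    "CGT": 6, "CGC": 3, "CGA": 4, "CGG": 3, "AGA": 14, "AGG": 10,
    "TCT": 16, "TCC": 8, "TCA": 12, "TCG": 4, "AGT": 10, "AGC": 8,
    "ACT": 14, "ACC": 8, "ACA": 12, "ACG": 4,
    "GTT": 18, "GTC": 8, "GTA": 6, "GTG": 10,
    "TGG": 10,
    "TAT": 12, "TAC": 8,
}
_CODONS = list(_CODON_WEIGHTS)
_CODON_P = np.array([_CODON_WEIGHTS[c] for c in _CODONS], dtype=float)
_CODON_P /= _CODON_P.sum()

STOP_CODONS = ("TAA", "TAG", "TGA")


class ConfigError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass
class SynthConfig:
    """Parameters of a synthetic study.

    Defaults describe the study conditions emulated throughout the test
    suite: five tissues, three replicates, moderate negative-binomial
    over-dispersion (variance = mu + alpha*mu^2 with alpha=0.1) and strongly
    correlated co-expression modules.
    """

    seed: int = 0
    n_genes: int = 120
    isoform_pairs: int = 8
    gap_lengths: Sequence[int] = (150, 200, 250, 80, 120, 60, 300, 180)
    flank_lengths: tuple[int, int] = (1200, 1200)
    n_duplicates: int = 6
    duplicate_identity: float = 0.995
    ssr_plants: Sequence[tuple[str, int]] = (("A", 12), ("AG", 8), ("ATC", 6))
    coding_fraction: float = 0.5
    n_tissues: int = 5
    n_reps: int = 3
    n_modules: int = 3
    module_size: int = 30
    within_module_cor: float = 0.9
    trait_link_strength: float = 0.9
    nb_dispersion: float = 0.1
    n_de_genes: int = 10
    de_log2fc: float = 3.0
    # Optional sampling ranges; when set they override the fixed lists above
    # for per-pair flank and gap draws.
    flank_range: Optional[tuple[int, int]] = None
    gap_range: Optional[tuple[int, int]] = None

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_tissues <= 0 or self.n_reps <= 0:
            raise ConfigError("sizes must be positive")
        if self.isoform_pairs < 0 or self.n_duplicates < 0:
            raise ConfigError("counts must be non-negative")
        if not (0.9 < self.duplicate_identity <= 1.0):
            raise ConfigError("duplicate_identity must lie in (0.9, 1.0]")
        if not (0.0 <= self.coding_fraction <= 1.0):
            raise ConfigError("coding_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if self.gap_lengths is not None and any(g <= 0 for g in self.gap_lengths):
            raise ConfigError("gap lengths must be positive")
        if any(f <= 0 for f in self.flank_lengths):
            raise ConfigError("flank lengths must be positive")


@dataclass
class Transcript:
    id: str
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class TruthSet:
    """Planted features, recorded at generation time.

    ``planted_as`` holds (long_id, short_id, gap_start, gap_end,
    should_be_called); the flag is derived by :func:`as_geometry_callable`,
    an arithmetic restatement of the splice-calling rules applied to the
    planted coordinates rather than to any alignment output.
    """

    planted_as: list = field(default_factory=list)
    planted_ssrs: list = field(default_factory=list)
    planted_orfs: list = field(default_factory=list)
    duplicate_groups: list = field(default_factory=list)
    module_labels: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)
    coding_ids: list = field(default_factory=list)
    noncoding_ids: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def as_geometry_callable(
    flank5: int,
    flank3: int,
    gap: int,
    min_hsp_len: int = 1000,
    min_gap: int = 100,
    min_end_distance: int = 100,
) -> bool:
    """Decide from planted geometry whether an isoform pair must be called.

    A pair yields an AS event iff each shared flank exceeds ``min_hsp_len``
    (it is the HSP), the insertion exceeds ``min_gap``, and the gap interval
    sits at least ``min_end_distance`` from both ends of the long isoform.
    The function is pure arithmetic on planted coordinates and shares no code
    with the alignment-based caller.
    """
    return (
        flank5 > min_hsp_len
        and flank3 > min_hsp_len
        and gap > min_gap
        and flank5 >= min_end_distance
        and flank3 >= min_end_distance
    )


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCS[rng.integers(0, 4, size=n)])


def _coding_region(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + biased-usage sense codons + stop; length 3*(n_codons+2)."""
    body = rng.choice(len(_CODONS), size=n_codons, p=_CODON_P)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(_CODONS[i] for i in body) + stop


def _pick_other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[rng.integers(0, len(choices))]


def generate_transcripts(config: SynthConfig) -> tuple[list[Transcript], TruthSet]:
    """Generate the synthetic transcript set and its truth sidecar.

    Layout of the set, in deterministic id order:

    * ``G####`` background genes (coding_fraction of them carry a planted ORF;
      the rest are nucleotide permutations of a coding-like draw),
    * ``ISO##L`` / ``ISO##S`` isoform pairs: flank5+insert+flank3 vs
      flank5+flank3, junction-adjacent bases pinned so local alignments
      cannot extend across the junction by chance,
    * ``<src>_dup#`` near-duplicates of noncoding, SSR-free background genes,
      mutated by point substitutions at rate 1 - duplicate_identity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts: list[Transcript] = []
    truth = TruthSet()

    n_coding = int(round(config.n_genes * config.coding_fraction))
    ssr_hosts: set[str] = set()

    for i in range(config.n_genes):
        tid = f"G{i:04d}"
        length = int(rng.integers(1200, 3001))
        if i < n_coding:
            # UTR5 + ORF + UTR3; ORF roughly 60% of the transcript.
            orf_nt = max(360, (int(length * 0.6) // 3) * 3)
            n_codons = orf_nt // 3 - 2
            utr5 = int(rng.integers(60, 200))
            cds = _coding_region(rng, n_codons)
            utr3 = max(0, length - utr5 - len(cds))
            seq = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
            truth.planted_orfs.append(
                [tid, utr5 % 3, utr5, utr5 + len(cds)]
            )
            truth.coding_ids.append(tid)
        else:
            # Noncoding: draw a coding-like sequence then permute every
            # nucleotide — base composition kept, codon/hexamer structure gone.
            proto = _coding_region(rng, max(1, length // 3 - 2))
            proto = proto[:length] if len(proto) >= length else proto + _rand_seq(
                rng, length - len(proto)
            )
            arr = np.array(list(proto))
            seq = "".join(arr[rng.permutation(len(arr))])
            truth.noncoding_ids.append(tid)
        transcripts.append(Transcript(tid, seq))

    # --- planted SSRs on noncoding background genes -----------------------
    noncoding_pool = list(truth.noncoding_ids)
    for k, (motif, repeats) in enumerate(config.ssr_plants):
        if k >= len(noncoding_pool):
            break
        tid = noncoding_pool[k]
        ssr_hosts.add(tid)
        t = next(t for t in transcripts if t.id == tid)
        unit = len(motif)
        tract = motif * repeats
        start = len(t.seq) // 2
        left = t.seq[: start - 1]
        right = t.seq[start + len(tract) + 1 :]
        # Pin the flanking bases so the planted run is exactly `repeats`
        # units: the left neighbour must not continue the period leftwards
        # and the right neighbour must not extend it.
        lb = _pick_other_base(rng, motif[-1])
        rb = _pick_other_base(rng, motif[0])
        t.seq = left + lb + tract + rb + right
        truth.planted_ssrs.append([tid, motif, repeats, start])

    # --- isoform pairs -----------------------------------------------------
    for k in range(config.isoform_pairs):
        if config.flank_range is not None:
            f5 = int(rng.integers(config.flank_range[0], config.flank_range[1] + 1))
            f3 = int(rng.integers(config.flank_range[0], config.flank_range[1] + 1))
        else:
            f5, f3 = config.flank_lengths
        if config.gap_range is not None:
            gap = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        else:
            gap = int(config.gap_lengths[k % len(config.gap_lengths)])
        flank5 = _rand_seq(rng, f5)
        flank3 = _rand_seq(rng, f3)
        insert = list(_rand_seq(rng, gap))
        # Pin junction bases: no chance HSP extension across the junction.
        insert[0] = _pick_other_base(rng, flank3[0])
        insert[-1] = _pick_other_base(rng, flank5[-1])
        insert = "".join(insert)
        long_id, short_id = f"ISO{k:02d}L", f"ISO{k:02d}S"
        transcripts.append(Transcript(long_id, flank5 + insert + flank3))
        transcripts.append(Transcript(short_id, flank5 + flank3))
        truth.planted_as.append(
            [long_id, short_id, f5, f5 + gap, as_geometry_callable(f5, f3, gap)]
        )

    # --- near-duplicates ---------------------------------------------------
    dup_pool = [tid for tid in truth.noncoding_ids if tid not in ssr_hosts]
    for k in range(config.n_duplicates):
        if k >= len(dup_pool):
            break
        src = next(t for t in transcripts if t.id == dup_pool[k])
        n_sub = max(1, int(round(len(src.seq) * (1 - config.duplicate_identity))))
        pos = rng.choice(len(src.seq), size=n_sub, replace=False)
        arr = np.array(list(src.seq))
        for p in pos:
            arr[p] = _pick_other_base(rng, arr[p])
        dup_id = f"{src.id}_dup1"
        transcripts.append(Transcript(dup_id, "".join(arr)))
        truth.duplicate_groups.append([src.id, dup_id])

    # --- module labels and DE genes ----------------------------------------
    gene_ids = [t.id for t in transcripts]
    n_module_genes = config.n_modules * config.module_size
    if n_module_genes > len(gene_ids):
        raise ConfigError("not enough transcripts for the requested modules")
    order = rng.permutation(len(gene_ids))
    module_gene_ids = [gene_ids[i] for i in order[:n_module_genes]]
    for j, gid in enumerate(module_gene_ids):
        truth.module_labels[gid] = j // config.module_size
    non_module = [gid for gid in gene_ids if gid not in truth.module_labels]
    for gid in non_module[: config.n_de_genes]:
        tissue = int(rng.integers(0, config.n_tissues))
        truth.de_genes[gid] = [tissue, float(config.de_log2fc)]

    return transcripts, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, variance mu + alpha*mu^2) via gamma-Poisson mixing."""
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


def generate_counts(
    config: SynthConfig, truth: TruthSet, transcripts: Optional[Sequence[Transcript]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the tissue x replicate count matrix and the trait table.

    Counts follow a negative-binomial model around gene/tissue means.  Genes
    in the same module share a tissue-level latent factor; the loading is set
    so that the expected pairwise within-module correlation approximates
    ``within_module_cor`` given the NB noise floor.  The first trait (GA3) is
    ``link*factor + (1-link)*noise`` on module 0's factor; the remaining
    traits are independent noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    if transcripts is not None:
        gene_ids = [t.id for t in transcripts]
    else:
        gene_ids = sorted(
            set(truth.module_labels)
            | set(truth.de_genes)
            | set(truth.coding_ids)
            | set(truth.noncoding_ids)
        )
    samples = [
        f"T{t + 1}_{r + 1}" for t in range(config.n_tissues) for r in range(config.n_reps)
    ]
    n_g, n_t, n_r = len(gene_ids), config.n_tissues, config.n_reps

    base = np.exp(rng.normal(np.log(300.0), 0.7, size=n_g))
    # Tissue-level latent factors, orthogonalized across modules so distinct
    # regulatory programs stay linearly independent (identifiable) even with
    # only a handful of tissues.
    raw = rng.normal(size=(config.n_modules, n_t))
    if config.n_modules > 1 and config.n_modules <= n_t:
        q, _ = np.linalg.qr(raw.T)
        factors = q.T[: config.n_modules] * np.sqrt(n_t)
    else:
        factors = raw

    # Loading chosen so that shared-factor variance over (shared + NB noise)
    # variance on the log scale approximates the target correlation.
    mu_typ = 300.0
    s2 = np.log1p(1.0 / mu_typ + config.nb_dispersion)
    r = min(max(config.within_module_cor, 0.0), 0.999)
    loading = np.sqrt(r / (1.0 - r) * s2) if r > 0 else 0.0

    log_mu = np.tile(np.log(base)[:, None], (1, n_t))
    for gi, gid in enumerate(gene_ids):
        m = truth.module_labels.get(gid)
        if m is not None:
            log_mu[gi] += loading * factors[m] - 0.5 * loading**2
        de = truth.de_genes.get(gid)
        if de is not None:
            tissue, lfc = de
            log_mu[gi, int(tissue)] += np.log(2.0) * lfc

    mu = np.exp(log_mu)
    counts = np.empty((n_g, n_t * n_r), dtype=np.int64)
    for t in range(n_t):
        for rep in range(n_r):
            counts[:, t * n_r + rep] = _nb_draw(rng, mu[:, t], config.nb_dispersion)

    count_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    count_df.index.name = "gene"

    trait_names = ["GA3", "sugar", "starch", "lignin", "ZT", "IAA", "ABA"]
    link = config.trait_link_strength
    tissue_of = np.repeat(np.arange(n_t), n_r)
    traits = pd.DataFrame(
        rng.normal(size=(len(samples), len(trait_names))),
        index=samples,
        columns=trait_names,
    )
    traits.index.name = "sample"
    if config.n_modules > 0:
        traits["GA3"] = link * factors[0][tissue_of] + (1.0 - link) * traits["GA3"].to_numpy()
    return count_df, traits


def make_module_expression(
    n_modules: int = 3,
    module_size: int = 30,
    n_samples: int = 15,
    within_cor: float = 0.9,
    n_background: int = 0,
    hub_loading: Optional[float] = None,
    n_hubs_per_module: int = 0,
    trait_link_strength: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, np.ndarray]:
    """Gaussian block-correlated expression with per-sample latent factors.

    Each module gene is ``l*f_m + sqrt(1-l^2)*eps`` with ``l = sqrt(within_cor)``
    so that the population pairwise correlation inside a module equals
    ``within_cor`` exactly.  Optionally the first ``n_hubs_per_module`` genes
    of each module get loading ``hub_loading`` (e.g. 0.995) to plant hub
    genes.  The trait is ``link*f_0 + (1-link)*noise``.

    Returns (expression genes x samples, module labels, trait, factors).
    """
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_modules, n_samples))
    rows, labels, ids = [], [], []
    l_base = np.sqrt(within_cor)
    for m in range(n_modules):
        for g in range(module_size):
            l = hub_loading if (hub_loading is not None and g < n_hubs_per_module) else l_base
            eps = rng.normal(size=n_samples)
            rows.append(l * factors[m] + np.sqrt(1.0 - l * l) * eps)
            labels.append(m)
            ids.append(f"M{m}_{g:03d}")
    for b in range(n_background):
        rows.append(rng.normal(size=n_samples))
        labels.append(-1)
        ids.append(f"BG_{b:03d}")
    samples = [f"S{j:02d}" for j in range(n_samples)]
    expr = pd.DataFrame(np.asarray(rows), index=ids, columns=samples)
    link = trait_link_strength
    trait = pd.Series(
        link * factors[0] + (1.0 - link) * rng.normal(size=n_samples),
        index=samples,
        name="GA3",
    )
    return expr, pd.Series(labels, index=ids, name="module"), trait, factors


# ---------------------------------------------------------------------------
# I/O helpers


def write_fasta(transcripts: Sequence[Transcript], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), 70):
                fh.write(t.seq[i : i + 70] + "\n")


def read_fasta(path) -> list[Transcript]:
    from Bio import SeqIO

    return [Transcript(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t")
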