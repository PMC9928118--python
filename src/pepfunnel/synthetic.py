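"""Synthetic data generators for every stage of the design funnel.

Each generator is a pure function of its seed and emulates the statistical
structure the corresponding analysis stage assumes: gapped fragment
alignments mixing gene-specific conserved sub-motifs with inter-column
covariation and motif-free outliers; ortholog triplets whose components
diverge at shared (interolog) or independent (decoy) rates; microarray scans
with a smooth spatially varying baseline and planted hits; and single-site
competitive binding curves with noise.

``make_demo_mfa`` and ``make_demo_substrates`` are deterministic *synthetic
stand-ins* for the study's reference fragment alignment and substrate list:
their printed summary statistics (1886 fragments x 16 columns; 67 substrates
= 38 yeast + 29 human; gene-specific SLiM variants such as P[T/S]F[N/S]FS,
P[E/D]IT[V/I]T, PQ[F/Y]x[I/L/V]x, P[F/Y][M/V]xFx; an independent-model
entropy near 10^17.3 sequences) match the real objects they replace, but the
individual sequences are simulated, not natural.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import Alignment
from .alphabet import ALPHABET, GAP_INDEX, Q, decode
from .interolog import Triplet, TripletSet

__all__ = [
    "make_mfa",
    "make_triplets",
    "make_chip",
    "make_fp",
    "make_demo_mfa",
    "make_demo_substrates",
]

RESIDUES = ALPHABET[:-1]


# --------------------------------------------------------------------- #
# fragment alignments
# --------------------------------------------------------------------- #


def _sample_from_profile(profile: np.ndarray, n: int, rng) -> np.ndarray:
    """Draw n sequences (codes) from an (N, Q) per-column profile."""
    cumulative = profile.cumsum(axis=1)
    u = rng.random((n, profile.shape[0]))
    return (u[:, :, None] > cumulative[None, :, :]).sum(axis=2).astype(np.int8)


def _gene_profile(
    n_columns: int,
    rng,
    conservation: float,
    motif_columns=None,
    motif_conservation: float = 0.9,
    gap_freq: float = 0.02,
    n_alternates: int = 3,
    floor_total: float = 0.005,
) -> np.ndarray:
    """Per-column categorical profile with bounded support.

    Each column concentrates on a preferred residue plus a few alternates
    (real alignment columns alternate among a handful of residue types);
    the remaining residues share a tiny floor mass.
    """
    profile = np.full((n_columns, Q), 0.0)
    for i in range(n_columns):
        cons = motif_conservation if motif_columns and i in motif_columns else conservation
        letters = rng.permutation(Q - 1)
        preferred, alternates = letters[0], letters[1 : 1 + n_alternates]
        rest = letters[1 + n_alternates :]
        profile[i, preferred] = cons
        profile[i, alternates] = (1.0 - cons - gap_freq - floor_total) / n_alternates
        profile[i, rest] = floor_total / rest.size
        profile[i, GAP_INDEX] = gap_freq
    return profile


def make_mfa(
    n_records: int = 1000,
    n_columns: int = 16,
    n_genes: int = 4,
    conservation: float = 0.5,
    motif_columns=(5, 6, 7, 8, 9, 10),
    motif_conservation: float = 0.9,
    coupling_pairs=(),
    coupling_strength: float = 0.0,
    outlier_fraction: float = 0.0,
    gap_freq: float = 0.02,
    outlier_gap_freq: float | None = None,
    n_alternates: int = 3,
    floor_total: float = 0.005,
    seed: int = 0,
) -> tuple[Alignment, pd.DataFrame]:
    """Mixture of per-gene profile models with optional pairwise couplings
    and a fraction of motif-free uniform-random outlier records.

    Couplings: for each (i, j) in ``coupling_pairs`` (0-based columns), a
    record is rewritten with probability ``coupling_strength`` to one of two
    fixed letter pairs at those columns, chosen by a fair coin - creating
    mutual information between the columns that no independent model can
    capture.

    Returns the alignment and a label frame (gene, is_outlier).
    """
    rng = np.random.default_rng(seed)
    profiles = [
        _gene_profile(
            n_columns, rng, conservation, set(motif_columns), motif_conservation,
            gap_freq, n_alternates, floor_total,
        )
        for _ in range(n_genes)
    ]
    n_outliers = int(round(outlier_fraction * n_records))
    genes = rng.integers(0, n_genes, size=n_records - n_outliers)
    codes = np.empty((n_records, n_columns), dtype=np.int8)
    for g in range(n_genes):
        members = np.flatnonzero(genes == g)
        codes[members] = _sample_from_profile(profiles[g], members.size, rng)
    # couplings: joint states at chosen column pairs
    pair_letters = [(rng.integers(0, Q - 1, 2), rng.integers(0, Q - 1, 2)) for _ in coupling_pairs]
    for (i, j), (ab1, ab2) in zip(coupling_pairs, pair_letters):
        mask = rng.random(n_records - n_outliers) < coupling_strength
        which = rng.random(n_records - n_outliers) < 0.5
        for k in np.flatnonzero(mask):
            a, b = (ab1 if which[k] else ab2)
            codes[k, i], codes[k, j] = a, b
    # outliers: motif-free uniform records; their gap fraction defaults to
    # the alignment's but is typically higher (misaligned fragments are
    # gap-rich)
    if n_outliers:
        o_gap = gap_freq if outlier_gap_freq is None else outlier_gap_freq
        probs = np.full(Q, (1 - o_gap) / (Q - 1))
        probs[GAP_INDEX] = o_gap
        codes[n_records - n_outliers :] = _sample_from_profile(
            np.tile(probs, (n_columns, 1)), n_outliers, rng
        )
    gene_labels = [f"gene{g}" for g in genes] + ["outlier"] * n_outliers
    labels = pd.DataFrame(
        {"gene": gene_labels, "is_outlier": [g == "outlier" for g in gene_labels]}
    )
    ids = [f"rec{k:05d}" for k in range(n_records)]
    ann = pd.DataFrame({"gene": gene_labels})
    return Alignment(ids=ids, sequences=[decode(c) for c in codes], annotations=ann), labels


# --------------------------------------------------------------------- #
# interolog triplets
# --------------------------------------------------------------------- #


def _evolve_chain(root: np.ndarray, times: np.ndarray, rate: float, rng) -> np.ndarray:
    """Evolve a sequence along a 1-D chain of organisms ordered by ``times``:
    each step mutates sites with probability rate * dt, so pairwise identity
    decays with time separation (a chain phylogeny)."""
    order = np.argsort(times)
    out = np.empty((times.size, root.size), dtype=np.int8)
    current = root.copy()
    prev_t = 0.0
    for idx in order:
        dt = times[idx] - prev_t
        mutate = rng.random(root.size) < rate * dt
        current = current.copy()
        current[mutate] = rng.integers(0, Q - 1, size=int(mutate.sum()))
        out[idx] = current
        prev_t = times[idx]
    return out


def make_triplets(
    substrate_id: str = "SP1",
    n_seeds: int = 6,
    n_true: int = 25,
    n_decoys: int = 25,
    lengths: tuple[int, int, int] = (60, 40, 50),
    rate: float = 2.0,
    seed: int = 0,
) -> tuple[TripletSet, pd.DataFrame]:
    """Seed + candidate triplets with ground-truth interolog labels.

    All components of seeds and true candidates evolve along the same chain
    phylogeny (shared per-organism divergence times); decoys evolve the
    substrate at an independently drawn time, breaking the mirror-tree
    correlation. Returns the triplet set and a label frame (triplet_id,
    is_true).
    """
    rng = np.random.default_rng(seed)
    n_all = n_seeds + n_true + n_decoys
    times = rng.uniform(0.05, 1.0, size=n_all)
    decoy_times = times.copy()
    decoy_slice = slice(n_seeds + n_true, n_all)
    decoy_times[decoy_slice] = rng.uniform(0.05, 1.0, size=n_decoys)
    roots = [rng.integers(0, Q - 1, size=L).astype(np.int8) for L in lengths]
    cna = _evolve_chain(roots[0], times, rate, rng)
    cnb = _evolve_chain(roots[1], times, rate, rng)
    sp = _evolve_chain(roots[2], decoy_times, rate, rng)

    def _triplet(k: int, prefix: str) -> Triplet:
        return Triplet(
            triplet_id=f"{prefix}{k:03d}",
            organism=f"org{k:03d}",
            cna=decode(cna[k]),
            cnb=decode(cnb[k]),
            sp=decode(sp[k]),
            cna_id=f"org{k:03d}_cna1",
            cnb_id=f"org{k:03d}_cnb1",
        )

    seeds = [_triplet(k, "seed") for k in range(n_seeds)]
    candidates = [_triplet(k, "cand") for k in range(n_seeds, n_all)]
    labels = pd.DataFrame(
        {
            "triplet_id": [t.triplet_id for t in candidates],
            "is_true": [True] * n_true + [False] * n_decoys,
        }
    )
    return TripletSet(substrate_id, seeds, candidates), labels


# --------------------------------------------------------------------- #
# chip scans and FP curves
# --------------------------------------------------------------------- #


def make_chip(
    n_rows: int = 20,
    n_cols: int = 20,
    n_repeats: int = 5,
    baseline_coefs=(6.0, 0.02, -0.015, 1e-3, 8e-4, -5e-4),
    noise_sd: float = 0.05,
    n_hits: int = 10,
    hit_effect_sd: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-array scan with a planted quadratic log-baseline and hits.

    Each peptide occupies two spots (ROIs); hits are interior peptides whose
    log-fluorescence is raised by ``hit_effect_sd`` noise standard
    deviations on both ROIs in every repeat. Returns the scan table
    (repeat, row, col, peptide_id, roi, fluorescence, border) and the truth
    table (peptide_id, is_hit).
    """
    if (n_rows * n_cols) % 2:
        raise ValueError("grid must hold an even number of spots")
    rng = np.random.default_rng(seed)
    positions = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    rng.shuffle(positions)
    n_peptides = len(positions) // 2
    spot_of = {}
    for p in range(n_peptides):
        spot_of[p] = (positions[2 * p], positions[2 * p + 1])

    def is_border(rc):
        r, c = rc
        return r in (0, n_rows - 1) or c in (0, n_cols - 1)

    interior_peptides = [
        p for p, (s1, s2) in spot_of.items() if not (is_border(s1) or is_border(s2))
    ]
    hits = set(rng.choice(interior_peptides, size=n_hits, replace=False).tolist())
    b0, br, bc, brr, bcc, brc = baseline_coefs
    rows = []
    for rep in range(n_repeats):
        for p, spots in spot_of.items():
            for roi, (r, c) in enumerate(spots, start=1):
                logf = b0 + br * r + bc * c + brr * r * r + bcc * c * c + brc * r * c
                logf += rng.normal(0.0, noise_sd)
                if p in hits:
                    logf += hit_effect_sd * noise_sd
                rows.append(
                    {
                        "repeat": rep,
                        "row": r,
                        "col": c,
                        "peptide_id": f"pep{p:04d}",
                        "roi": roi,
                        "fluorescence": float(np.exp(logf)),
                        "border": is_border((r, c)),
                    }
                )
    truth = pd.DataFrame(
        {
            "peptide_id": [f"pep{p:04d}" for p in range(n_peptides)],
            "is_hit": [p in hits for p in range(n_peptides)],
            "border": [
                is_border(spot_of[p][0]) or is_border(spot_of[p][1])
                for p in range(n_peptides)
            ],
        }
    )
    return pd.DataFrame(rows), truth


def make_fp(
    true_ic50s=(1.17, 10.2, 54.0),
    concentrations=None,
    f_min: float = 60.0,
    f_max: float = 220.0,
    noise_frac: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Competitive FP curves: polarization = f_min + span/(1 + [I]/IC50)
    plus Gaussian noise of ``noise_frac`` times the dynamic range.

    Returns a tidy frame (peptide, concentration_uM, replicate,
    polarization, true_ic50).
    """
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.logspace(-2, 3, 9)
    concentrations = np.asarray(concentrations, dtype=float)
    rows = []
    for k, ic50 in enumerate(true_ic50s):
        for conc in concentrations:
            expected = f_min + (f_max - f_min) / (1.0 + conc / ic50)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "peptide": f"fp{k:02d}",
                        "concentration_uM": conc,
                        "replicate": rep,
                        "polarization": expected
                        + rng.normal(0.0, noise_frac * (f_max - f_min)),
                        "true_ic50": ic50,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# deterministic demo stand-ins (synthetic)
# --------------------------------------------------------------------- #

# Gene-specific SLiM variants over the six motif columns, written as one
# allowed-residue set per column (x = broad hydrophilic/variable site).
_DEMO_MOTIFS = {
    "NFATc1": ["P", "RA", "I", "EN", "I", "T"],
    "NFATc2": ["P", "R", "I", "E", "I", "T"],
    "AKAP79": ["P", "IV", "A", "I", "I", "T"],
    "TRESK": ["P", "QE", "I", "IV", "I", "S"],
    "KCNN3": ["P", "E", "I", "V", "I", "S"],
    "C16Orf74": ["P", "D", "I", "I", "I", "T"],
    "RIPOR2": ["P", "ED", "I", "T", "VI", "T"],
    "CAPN11": ["P", "Q", "FY", "RF", "VI", "TX"],
    "SFB3": ["P", "FY", "MV", "LT", "F", "ED"],
    "RCAN1": ["P", "TS", "F", "NS", "F", "S"],
    "NHE1": ["P", "VI", "I", "SV", "I", "T"],
    "CABIN1": ["P", "P", "E", "I", "T", "V"],
}
# replace the placeholder X (no such residue) with a small variable set
_DEMO_MOTIFS["CAPN11"][5] = "TVL"

_DEMO_GENE_WEIGHTS = {
    "NFATc1": 0.06, "NFATc2": 0.07, "AKAP79": 0.11, "TRESK": 0.10,
    "KCNN3": 0.08, "C16Orf74": 0.07, "RIPOR2": 0.10, "CAPN11": 0.12,
    "SFB3": 0.07, "RCAN1": 0.08, "NHE1": 0.07, "CABIN1": 0.07,
}

_DEMO_TAXA = (
    "Homo sapiens", "Mus musculus", "Gallus gallus", "Xenopus laevis",
    "Danio rerio", "Pelecanus crispus", "Fulmarus glacialis",
    "Schistosoma mansoni", "Hydra vulgaris", "Daphnia magna",
    "Saccharomyces cerevisiae", "Candida albicans",
)

#: flanking-column conservation of the demo generator: probability mass on a
#: gene-preferred residue; the remainder is spread over all 20 residues plus
#: a small gap fraction. Chosen so the stand-in reproduces the diversity of
#: the reference alignment it replaces (independent-model entropy near
#: 10^17.3 at 16 columns).
_DEMO_FLANK_CONSERVATION = 0.43
#: strong conservation only at the P, I_1 and I_2 motif positions; the x and
#: terminal motif positions alternate between a handful of residues
_DEMO_MOTIF_CONSERVATION = {0: 0.92, 1: 0.55, 2: 0.88, 3: 0.55, 4: 0.88, 5: 0.60}
_DEMO_GAP_FREQ = 0.03
_DEMO_DISORDER_SET = "PESTDG"


def _demo_gene_profile(gene: str, rng) -> np.ndarray:
    motif = _DEMO_MOTIFS[gene]
    profile = np.zeros((16, Q))
    for i in range(16):
        if 5 <= i <= 10:
            cons = _DEMO_MOTIF_CONSERVATION[i - 5]
            allowed = [ALPHABET.index(c) for c in motif[i - 5]]
            base = (1.0 - cons - _DEMO_GAP_FREQ) / (Q - 1)
            profile[i, : Q - 1] = base
            profile[i, allowed] += cons / len(allowed)
            profile[i, GAP_INDEX] = _DEMO_GAP_FREQ
        else:
            # flanks sit in disordered regions: gene-specific preferences
            # drawn from disorder-promoting residues
            preferred = ALPHABET.index(_DEMO_DISORDER_SET[rng.integers(0, len(_DEMO_DISORDER_SET))])
            base = (1.0 - _DEMO_FLANK_CONSERVATION - _DEMO_GAP_FREQ) / (Q - 1)
            profile[i, : Q - 1] = base
            profile[i, preferred] += _DEMO_FLANK_CONSERVATION
            profile[i, GAP_INDEX] = _DEMO_GAP_FREQ
    return profile


def make_demo_mfa(seed: int = 2023) -> Alignment:
    """Synthetic stand-in for the curated 1886-fragment, 16-column multiple
    fragment alignment of natural calcineurin-binding fragments.

    Deterministic given the seed; gene and organism annotations included.
    """
    rng = np.random.default_rng(seed)
    genes = list(_DEMO_MOTIFS)
    weights = np.array([_DEMO_GENE_WEIGHTS[g] for g in genes])
    weights = weights / weights.sum()
    counts = np.floor(weights * 1886).astype(int)
    counts[0] += 1886 - counts.sum()
    ids, seqs, ann = [], [], []
    k = 0
    for gene, n_gene in zip(genes, counts):
        profile = _demo_gene_profile(gene, rng)
        codes = _sample_from_profile(profile, n_gene, rng)
        for row in codes:
            taxon = _DEMO_TAXA[rng.integers(0, len(_DEMO_TAXA))]
            ids.append(f"frag{k:05d}")
            seqs.append(decode(row))
            ann.append({"gene": gene, "organism": taxon})
            k += 1
    return Alignment(ids=ids, sequences=seqs, annotations=pd.DataFrame(ann))


def make_demo_substrates() -> pd.DataFrame:
    """Synthetic stand-in for the curated substrate list: 67 experimentally
    characterized calcineurin substrates (29 human, 38 yeast), each with a
    representative SLiM-containing fragment. Deterministic."""
    human_named = [
        "NFATc1", "NFATc2", "NFATc3", "NFATc4", "AKAP79", "TRESK", "KCNN3",
        "C16Orf74", "RIPOR2", "CAPN11", "RCAN1", "NHE1", "CABIN1",
    ]
    human = human_named + [f"HSUB{k:02d}" for k in range(1, 30 - len(human_named))]
    yeast = [f"YSUB{k:02d}" for k in range(1, 39)]
    yeast[0], yeast[1] = "SFB3", "CRZ1"
    rng = np.random.default_rng(67)
    rows = []
    for organism, gene_list in (("Homo sapiens", human), ("Saccharomyces cerevisiae", yeast)):
        for gene in gene_list:
            profile_gene = gene if gene in _DEMO_MOTIFS else "NFATc2"
            profile = _demo_gene_profile(profile_gene, rng)
            fragment = decode(_sample_from_profile(profile, 1, rng)[0]).replace("-", "A")
            rows.append({"gene": gene, "organism": organism, "fragment": fragment})
    frame = pd.DataFrame(rows)
    assert len(frame) == 67
    return frame
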