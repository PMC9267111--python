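"""Synthetic CDS generation with controlled codon-usage structure.

A :class:`CodonModel` fixes amino-acid frequencies, per-family synonymous
codon distributions (Dirichlet-drawn, with an exponential tilt toward
G/C-ending codons calibrated so the model-expected GC3 hits a target), and
an optional CpG depletion factor.  Sequences are i.i.d. codon draws wrapped
in ATG ... stop, so every generated CDS passes validation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .genetic_code import AA_TO_CODONS, MULTI_CODON_AAS, SENSE_CODONS, STOP_CODONS
from .seqio import HOST, VIRUS, CodingSequence, write_cds_fasta

_GC3_TOL = 0.005
_TILT_RANGE = 80.0


@dataclass(frozen=True)
class CodonModel:
    """Generative model over sense codons."""

    aa_freqs: Mapping[str, float]
    within_family: Mapping[str, Mapping[str, float]]
    target_gc3: float
    bias_strength: float
    cpg_depletion: float = 1.0
    #: calibrated per-CpG acceptance factor used by the sampler so that the
    #: generated sequences' expected rho_CG equals cpg_depletion
    cpg_accept: float = 1.0

    def codon_probs(self) -> dict[str, float]:
        """Joint sampling probability of each sense codon (pre-depletion)."""
        probs = {}
        for aa, w in self.aa_freqs.items():
            for codon, q in self.within_family[aa].items():
                probs[codon] = w * q
        return probs

    def expected_gc3(self) -> float:
        """Model-expected third-position G/C fraction over the multi-codon
        amino acids (the GC3s-like quantity the tilt is calibrated on)."""
        return _expected_gc3(self.aa_freqs, self.within_family)


@dataclass(frozen=True)
class StudyDesign:
    n_host_genes: int = 1000
    n_viruses: int = 10
    similar_fraction: float = 0.05
    gene_length_codons: tuple[int, int] = (300, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host_genes < 1 or self.n_viruses < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.similar_fraction <= 1.0:
            raise ValueError("similar_fraction must be in [0, 1]")
        lo, hi = self.gene_length_codons
        if lo < 100 or hi < lo:
            raise ValueError("gene_length_codons must satisfy 100 <= lo <= hi")


def default_aa_freqs(met_trp_weight: float = 0.01) -> dict[str, float]:
    """Uniform over the 18 multi-codon amino acids plus small Met/Trp weights."""
    rest = (1.0 - 2.0 * met_trp_weight) / len(MULTI_CODON_AAS)
    freqs = {aa: rest for aa in MULTI_CODON_AAS}
    freqs["M"] = met_trp_weight
    freqs["W"] = met_trp_weight
    return freqs


def _ends_gc(codon: str) -> bool:
    return codon[2] in "GC"


def _expected_gc3(
    aa_freqs: Mapping[str, float], within: Mapping[str, Mapping[str, float]]
) -> float:
    num = 0.0
    den = 0.0
    for aa in MULTI_CODON_AAS:
        w = aa_freqs.get(aa, 0.0)
        den += w
        num += w * sum(q for c, q in within[aa].items() if _ends_gc(c))
    if den == 0:
        raise ValueError("amino-acid frequencies put no mass on multi-codon families")
    return num / den


def _tilt(
    within: Mapping[str, Mapping[str, float]], t: float
) -> dict[str, dict[str, float]]:
    out = {}
    for aa, dist in within.items():
        weights = {c: q * np.exp(t if _ends_gc(c) else 0.0) for c, q in dist.items()}
        z = sum(weights.values())
        out[aa] = {c: w / z for c, w in weights.items()}
    return out


def make_codon_model(
    target_gc3: float,
    bias_strength: float,
    seed: int,
    aa_freqs: Optional[Mapping[str, float]] = None,
    cpg_depletion: float = 1.0,
) -> CodonModel:
    """Draw per-family codon distributions and calibrate them to ``target_gc3``.

    ``bias_strength = 0`` gives exactly uniform within-family usage; larger
    values draw from a symmetric Dirichlet with concentration
    ``1 / bias_strength``, concentrating usage on fewer codons.  The whole
    model is then exponentially tilted toward G/C-ending codons until its
    expected GC3 matches ``target_gc3`` within 0.005.
    """
    if not 0.0 <= target_gc3 <= 1.0:
        raise ValueError("target_gc3 must be in [0, 1]")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    if not 0.0 < cpg_depletion <= 1.0:
        raise ValueError("cpg_depletion must be in (0, 1]")
    if aa_freqs is None:
        aa_freqs = default_aa_freqs()
    rng = np.random.default_rng(seed)
    within: dict[str, dict[str, float]] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) == 1:
            within[aa] = {codons[0]: 1.0}
        elif bias_strength == 0.0:
            within[aa] = {c: 1.0 / len(codons) for c in codons}
        else:
            draw = rng.dirichlet(np.full(len(codons), 1.0 / bias_strength))
            within[aa] = dict(zip(codons, draw.tolist()))

    def gap(t: float) -> float:
        return _expected_gc3(aa_freqs, _tilt(within, t)) - target_gc3

    lo, hi = -_TILT_RANGE, _TILT_RANGE
    if gap(lo) > _GC3_TOL or gap(hi) < -_GC3_TOL:
        raise ValueError(
            f"target GC3 {target_gc3} unattainable with these family distributions"
        )
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    t = (lo + hi) / 2.0
    tilted = _tilt(within, t)
    achieved = _expected_gc3(aa_freqs, tilted)
    if abs(achieved - target_gc3) > _GC3_TOL:
        raise ValueError(
            f"calibration failed: achieved GC3 {achieved:.4f} vs target {target_gc3}"
        )
    model = CodonModel(
        aa_freqs=dict(aa_freqs),
        within_family=tilted,
        target_gc3=target_gc3,
        bias_strength=bias_strength,
        cpg_depletion=cpg_depletion,
    )
    if cpg_depletion < 1.0:
        accept = _calibrate_cpg_accept(model.codon_probs(), cpg_depletion)
        model = CodonModel(
            aa_freqs=model.aa_freqs,
            within_family=model.within_family,
            target_gc3=target_gc3,
            bias_strength=bias_strength,
            cpg_depletion=cpg_depletion,
            cpg_accept=accept,
        )
    return model


# per-codon CpG bookkeeping for the rejection sampler
_INTERNAL_CG = {c: (1 if c[:2] == "CG" else 0) + (1 if c[1:] == "CG" else 0) for c in SENSE_CODONS}
_STARTS_G = {c: c[0] == "G" for c in SENSE_CODONS}


def _chain_expected_rho_cg(codon_probs: Mapping[str, float], accept: float) -> float:
    """Expected rho_CG of the codon Markov chain induced by the rejection
    sampler with per-CpG acceptance factor ``accept``.

    The sampler's redraw-until-accept step renormalizes the tilted codon
    probabilities, so the realized CpG depletion is milder than the raw
    acceptance factor; this computes the long-sequence expectation exactly
    from the chain's stationary distribution.
    """
    codons = sorted(codon_probs)
    p = np.array([codon_probs[c] for c in codons])
    p = p / p.sum()
    internal = np.array([_INTERNAL_CG[c] for c in codons], dtype=float)
    starts_g = np.array([_STARTS_G[c] for c in codons], dtype=float)
    ends_c = np.array([c[2] == "C" for c in codons], dtype=float)
    # T[i, j] = P(next = j | prev = i)
    cg = internal[None, :] + ends_c[:, None] * starts_g[None, :]
    t = p[None, :] * accept**cg
    t /= t.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(t.T)
    pi = np.real(evecs[:, np.argmax(np.real(evals))])
    pi = np.abs(pi) / np.abs(pi).sum()
    e_internal = float(pi @ internal)
    e_boundary = float(pi @ (t * (ends_c[:, None] * starts_g[None, :])).sum(axis=1))
    f_cg = (e_internal + e_boundary) / 3.0
    counts_c = np.array([c.count("C") for c in codons], dtype=float)
    counts_g = np.array([c.count("G") for c in codons], dtype=float)
    f_c = float(pi @ counts_c) / 3.0
    f_g = float(pi @ counts_g) / 3.0
    return f_cg / (f_c * f_g)


def _calibrate_cpg_accept(codon_probs: Mapping[str, float], target_rho: float) -> float:
    """Acceptance factor whose chain-expected rho_CG equals ``target_rho``."""
    if _chain_expected_rho_cg(codon_probs, 1.0) < target_rho:
        raise ValueError(
            f"target rho_CG {target_rho} exceeds the model's undepleted expectation"
        )
    lo, hi = 1e-9, 1.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if _chain_expected_rho_cg(codon_probs, mid) < target_rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _as_rng(seed: int | Sequence[int] | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_cds(
    model: CodonModel,
    n_codons: int,
    seed: int | Sequence[int] | np.random.Generator,
    seq_id: str = "synthetic",
    origin: str = HOST,
    **labels: str,
) -> CodingSequence:
    """ATG + ``n_codons`` i.i.d. model draws + one stop codon.

    With ``cpg_depletion = d < 1`` each candidate codon is accepted with
    probability d per CpG it would create (inside the codon or across the
    boundary with the previous one), thinning CG occurrence by roughly d.
    """
    if n_codons < 100:
        raise ValueError("n_codons must be >= 100 so the length filter passes")
    rng = _as_rng(seed)
    probs = model.codon_probs()
    codon_arr = np.array(sorted(probs))
    p = np.array([probs[c] for c in codon_arr])
    p = p / p.sum()
    d = model.cpg_accept if model.cpg_depletion < 1.0 else 1.0
    if d >= 1.0:
        body = codon_arr[rng.choice(len(codon_arr), size=n_codons, p=p)]
        body = body.tolist()
    else:
        body = []
        prev_ends_c = False  # ATG does not end with C
        batch = iter(())
        while len(body) < n_codons:
            try:
                c = str(next(batch))
            except StopIteration:
                batch = iter(codon_arr[rng.choice(len(codon_arr), size=512, p=p)])
                continue
            n_cg = _INTERNAL_CG[c] + (1 if prev_ends_c and _STARTS_G[c] else 0)
            if n_cg and rng.random() > d**n_cg:
                continue
            body.append(c)
            prev_ends_c = c[2] == "C"
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    sequence = "ATG" + "".join(body) + stop
    return CodingSequence(id=seq_id, sequence=sequence, origin=origin, **labels)


def generate_study(
    design: StudyDesign, virus_model: CodonModel, host_model: CodonModel
) -> tuple[list[CodingSequence], list[CodingSequence], dict[str, bool]]:
    """Planted-structure study: a ``similar_fraction`` of host genes is drawn
    from the virus model (ground truth recorded), the rest from the host
    model, and viruses from the virus model.

    Per-gene RNG streams are derived from ``design.seed`` and the gene index,
    so individual sequences do not depend on the collection sizes.
    """
    n_similar = round(design.similar_fraction * design.n_host_genes)
    assign_rng = np.random.default_rng([design.seed, 0])
    similar_idx = set(
        assign_rng.choice(design.n_host_genes, size=n_similar, replace=False).tolist()
    )
    lo, hi = design.gene_length_codons
    hosts: list[CodingSequence] = []
    truth: dict[str, bool] = {}
    width = len(str(design.n_host_genes))
    for i in range(design.n_host_genes):
        rng = np.random.default_rng([design.seed, 1, i])
        length = int(rng.integers(lo, hi + 1))
        model = virus_model if i in similar_idx else host_model
        gid = f"host_{i:0{width}d}"
        hosts.append(
            generate_cds(model, length, rng, seq_id=gid, origin=HOST, host_species="synthetic")
        )
        truth[gid] = i in similar_idx
    viruses: list[CodingSequence] = []
    vwidth = len(str(design.n_viruses))
    for j in range(design.n_viruses):
        rng = np.random.default_rng([design.seed, 2, j])
        length = int(rng.integers(lo, hi + 1))
        viruses.append(
            generate_cds(
                virus_model, length, rng,
                seq_id=f"virus_{j:0{vwidth}d}", origin=VIRUS, host_species="synthetic",
            )
        )
    return hosts, viruses, truth


def write_study(
    out_dir: str | Path,
    design: StudyDesign,
    hosts: list[CodingSequence],
    viruses: list[CodingSequence],
    truth: Mapping[str, bool],
) -> None:
    """Write host/virus FASTA, a truth-label TSV and a key=value design file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cds_fasta(hosts, out / "host.fasta")
    write_cds_fasta(viruses, out / "virus.fasta")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("id\tsimilar\n")
        for gid, flag in truth.items():
            fh.write(f"{gid}\t{int(flag)}\n")
    with open(out / "design.cfg", "w") as fh:
        for key, val in (
            ("n_host_genes", design.n_host_genes),
            ("n_viruses", design.n_viruses),
            ("similar_fraction", design.similar_fraction),
            ("gene_length_codons", f"{design.gene_length_codons[0]}-{design.gene_length_codons[1]}"),
            ("seed", design.seed),
        ):
            fh.write(f"{key} = {val}\n")
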