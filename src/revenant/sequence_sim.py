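"""Sequence simulation along gene trees (S mode).

Continuous-time Markov substitution models at three levels: nucleotide
(HKY85, with JC69 as its equal-rate special case), codon (a GY94-style
61-state model with transition/transversion ratio kappa and dN/dS ratio
omega over the standard genetic code), and amino acid (the LG empirical
model of Le & Gascuel 2008, or a Poisson equal-rates model).

Branch lengths of a gene tree are durations in simulation time; a global
scaling factor and optional per-branch multipliers convert them to expected
substitutions per site, which is how users simulate fast or slow evolving
families.  Sites evolve independently; there are no indels, so every leaf
sequence has the root length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import expm

from .gene_tree import GeneTree

__all__ = [
    "SubstitutionModel",
    "BranchScaling",
    "scale_tree",
    "simulate_alignment",
]

NUCLEOTIDES = ("T", "C", "A", "G")
AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")

# Standard genetic code keyed by codon over TCAG ordering; '*' marks stops.
_CODE = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
ALL_CODONS = tuple(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES)
GENETIC_CODE = dict(zip(ALL_CODONS, _CODE))
SENSE_CODONS = tuple(c for c in ALL_CODONS if GENETIC_CODE[c] != "*")

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

# LG exchangeabilities (Le & Gascuel 2008), lower triangle column-major over
# the amino-acid order above, plus the model's stationary frequencies.
_LG_EXCH = np.array("""
    0.425093 0.276818 0.395144 2.489084 0.969894 1.038545 2.066040 0.358858
    0.149830 0.395337 0.536518 1.124035 0.253701 1.177651 4.727182 2.139501
    0.180717 0.218959 2.547870 0.751878 0.123954 0.534551 2.807908 0.363970
    0.390192 2.426601 0.126991 0.301848 6.326067 0.484133 0.052722 0.332533
    0.858151 0.578987 0.593607 0.314440 0.170887 5.076149 0.528768 1.695752
    0.541712 1.437645 4.509238 0.191503 0.068427 2.145078 0.371004 0.089525
    0.161787 4.008358 2.000679 0.045376 0.612025 0.083688 0.062556 0.523386
    5.243870 0.844926 0.927114 0.010690 0.015076 0.282959 0.025548 0.017416
    0.394456 1.240275 0.425860 0.029890 0.135107 0.037967 0.084808 0.003499
    0.569265 0.640543 0.320627 0.594007 0.013266 0.893680 1.105251 0.075382
    2.784478 1.143480 0.670128 1.165532 1.959291 4.128591 0.267959 4.813505
    0.072854 0.582457 3.234294 1.672569 0.035855 0.624294 1.223828 1.080136
    0.236199 0.257336 0.210332 0.348847 0.423881 0.044265 0.069673 1.807177
    0.173735 0.018811 0.419409 0.611973 0.604545 0.077852 0.120037 0.245034
    0.311484 0.008705 0.044261 0.296636 0.139538 0.089586 0.196961 1.739990
    0.129836 0.268491 0.054679 0.076701 0.108882 0.366317 0.697264 0.442472
    0.682139 0.508851 0.990012 0.584262 0.597054 5.306834 0.119013 4.145067
    0.159069 4.273607 1.112727 0.078281 0.064105 1.033739 0.111660 0.232523
    10.649107 0.137500 6.312358 2.592692 0.249060 0.182287 0.302936 0.619632
    0.299648 1.702745 0.656604 0.023918 0.390322 0.748683 1.136863 0.049906
    0.131932 0.185202 1.798853 0.099849 0.346960 2.020366 0.696175 0.481306
    1.898718 0.094464 0.361819 0.165001 2.457121 7.803902 0.654683 1.338132
    0.571468 0.095131 0.089613 0.296501 6.472279 0.248862 0.400547 0.098369
    0.140825 0.245841 2.188158 3.151815 0.189510 0.249313
""".split(), dtype=float)

_LG_FREQS = np.array([
    0.079066, 0.055941, 0.041977, 0.053052, 0.012937, 0.040767, 0.071586,
    0.057337, 0.022355, 0.062157, 0.099081, 0.064600, 0.022951, 0.042302,
    0.044040, 0.061197, 0.053287, 0.012066, 0.034155, 0.069147,
])


def _normalize_generator(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Set the diagonal and rescale so the mean rate is 1 substitution/site."""
    Q = Q.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    return Q / mean_rate


@dataclass
class SubstitutionModel:
    """A time-reversible substitution model: generator + stationary law.

    ``rate_matrix`` rows sum to zero and the generator is normalized so one
    unit of branch length is one expected substitution per site.
    """

    level: str  # NUCLEOTIDE | CODON | AMINO_ACID
    states: tuple[str, ...]
    rate_matrix: np.ndarray
    stationary_distribution: np.ndarray
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        Q, pi = self.rate_matrix, self.stationary_distribution
        if Q.shape != (len(self.states), len(self.states)):
            raise ValueError("rate matrix shape does not match the state space")
        if np.any(Q - np.diag(np.diag(Q)) < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
            raise ValueError("rate matrix rows must sum to 0")
        if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
            raise ValueError("stationary distribution must be a simplex vector")

    # -- constructors ----------------------------------------------------

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        """Jukes-Cantor: HKY with kappa=1 and equal base frequencies."""
        return cls.hky(kappa=1.0)

    @classmethod
    def hky(
        cls, kappa: float = 2.0, freqs: Optional[np.ndarray] = None
    ) -> "SubstitutionModel":
        """HKY85: transition/transversion ratio kappa, arbitrary frequencies."""
        pi = np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
        if kappa <= 0:
            raise ValueError("kappa must be > 0")
        Q = np.zeros((4, 4))
        for i, x in enumerate(NUCLEOTIDES):
            for j, y in enumerate(NUCLEOTIDES):
                if i == j:
                    continue
                rate = pi[j]
                if frozenset((x, y)) in _TRANSITIONS:
                    rate *= kappa
                Q[i, j] = rate
        return cls(
            "NUCLEOTIDE", NUCLEOTIDES, _normalize_generator(Q, pi), pi,
            {"kappa": kappa},
        )

    @classmethod
    def gy94(
        cls,
        kappa: float = 2.0,
        omega: float = 0.2,
        codon_freqs: Optional[np.ndarray] = None,
    ) -> "SubstitutionModel":
        """GY94-style codon model over the 61 sense codons.

        Single-nucleotide changes only; transitions are weighted by kappa
        and nonsynonymous changes by omega (dN/dS).
        """
        if kappa <= 0 or omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        n = len(SENSE_CODONS)
        pi = (
            np.full(n, 1.0 / n)
            if codon_freqs is None
            else np.asarray(codon_freqs, dtype=float)
        )
        Q = np.zeros((n, n))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                rate = pi[j]
                if frozenset(diffs[0]) in _TRANSITIONS:
                    rate *= kappa
                if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                    rate *= omega
                Q[i, j] = rate
        return cls(
            "CODON", SENSE_CODONS, _normalize_generator(Q, pi), pi,
            {"kappa": kappa, "omega": omega},
        )

    @classmethod
    def lg(cls, freqs: Optional[np.ndarray] = None) -> "SubstitutionModel":
        """LG amino-acid model with its published frequencies by default."""
        pi = _LG_FREQS.copy() if freqs is None else np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
        S = np.zeros((20, 20))
        k = 0
        for col in range(20):  # lower triangle, column-major
            for row in range(col + 1, 20):
                S[row, col] = S[col, row] = _LG_EXCH[k]
                k += 1
        Q = S * pi[None, :]
        return cls("AMINO_ACID", AMINO_ACIDS, _normalize_generator(Q, pi), pi, {})

    @classmethod
    def poisson_aa(cls) -> "SubstitutionModel":
        """Equal-rate amino-acid model (all exchanges equally likely)."""
        pi = np.full(20, 0.05)
        Q = np.ones((20, 20))
        return cls("AMINO_ACID", AMINO_ACIDS, _normalize_generator(Q, pi), pi, {})


@dataclass(frozen=True)
class BranchScaling:
    """Global and per-branch conversion from durations to substitutions/site."""

    global_factor: float = 1.0
    branch_factors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.global_factor <= 0:
            raise ValueError("global scaling factor must be > 0")
        for nid, f in self.branch_factors.items():
            if f <= 0:
                raise ValueError(f"branch factor for node {nid} must be > 0")

    def factor_for(self, node_id: int) -> float:
        return self.global_factor * self.branch_factors.get(node_id, 1.0)


def scale_tree(gt: GeneTree, scaling: BranchScaling) -> dict[int, float]:
    """Edge lengths in expected substitutions per site, keyed by child node."""
    return {
        nid: gt.branch_length(nid) * scaling.factor_for(nid)
        for nid in gt.nodes
        if gt.nodes[nid].parent is not None
    }


def _evolve_sequence(
    seq: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One edge: redraw every site from its row of the transition matrix."""
    out = np.empty_like(seq)
    for s in np.unique(seq):
        mask = seq == s
        out[mask] = rng.choice(P.shape[0], size=int(mask.sum()), p=P[s])
    return out


def simulate_alignment(
    gt: GeneTree,
    model: SubstitutionModel,
    root_length: int,
    seed: int | None = None,
    scaling: BranchScaling | None = None,
    include_all_leaves: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Simulate sequences down a gene tree; returns {leaf name: sequence}.

    The root sequence is drawn from the stationary distribution and each
    site evolves independently along each edge with transition matrix
    ``expm(length * Q)``.  ``root_length`` is in model states (codons for
    the codon level).  By default only PRESENT leaves are returned; with
    ``include_all_leaves`` extinct and lost tips are reported too.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if scaling is None:
        scaling = BranchScaling()
    lengths = scale_tree(gt, scaling)
    Q = model.rate_matrix
    pi = model.stationary_distribution

    # cache transition matrices per distinct edge length
    p_cache: dict[float, np.ndarray] = {}

    def P_of(length: float) -> np.ndarray:
        key = round(length, 12)
        if key not in p_cache:
            P = expm(length * Q) if length > 0 else np.eye(len(pi))
            P = np.clip(P, 0.0, None)
            p_cache[key] = P / P.sum(axis=1, keepdims=True)
        return p_cache[key]

    root_seq = rng.choice(len(pi), size=root_length, p=pi / pi.sum())
    sequences: dict[str, str] = {}

    def decode(arr: np.ndarray) -> str:
        return "".join(model.states[i] for i in arr)

    def walk(nid: int, seq: np.ndarray) -> None:
        node = gt.nodes[nid]
        if not node.children:
            if node.event == "PRESENT" or include_all_leaves:
                sequences[node.leaf_name] = decode(seq)
            return
        for c in node.children:
            child_seq = _evolve_sequence(seq, P_of(lengths[c]), rng)
            walk(c, child_seq)

    walk(gt.root_id, root_seq)
    return sequences
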