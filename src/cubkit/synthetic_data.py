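"""Synthetic coding-sequence generator with known mutation/selection truth.

A generative snapshot model (no evolutionary dynamics): each gene draws a
third-position GC equilibrium ``g`` from a Beta distribution (gene-to-gene
mutation-pressure variation) and, residue by residue, picks a synonymous
codon from the mixture

    (1 − s) · mutation-driven distribution  +  s · point mass on the
    family's preferred codon,

where the mutation-driven distribution puts probability ``g`` on GC-ending
and ``1 − g`` on AT-ending codons of the family (split evenly within each
ending class, A/T and G/C symmetric).  ``s`` is the selection strength; an
optional high-expression gene class gets a stronger ``s``.

Amino-acid usage is fixed to a plant-like average composition — except in
the ``free`` amino-acid mode used by the mutation-only preset, where
positions 1 and 2 also follow the gene's GC equilibrium (amino-acid
composition drifts with mutation pressure).  That mechanism is what makes
GC12 track GC3 with slope near 1, the textbook neutral regime; with a
fixed proteome the neutrality slope is necessarily near 0.

Every simulated gene starts with ATG, ends with a single stop drawn from
TGA/TAA/TAG weights (default 0.40/0.35/0.25, TGA-preferring as in plant
nuclear genomes), contains no internal stop, and passes the CDS filter by
construction.  Identical (scenario, seed) gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, CODONS, GENETIC_CODE, STOP_CODONS
from .sequence_io import CodingSequence, write_fasta

__all__ = [
    "SimulationScenario",
    "simulate_genes",
    "simulate_panel",
    "preset_scenarios",
    "PREFERRED_AT_ENDING",
    "PREFERRED_GC_ENDING",
    "AA_FREQUENCIES",
]

#: plant-like average amino-acid composition (fractions, sum to 1)
AA_FREQUENCIES: dict[str, float] = {
    "A": 0.063, "R": 0.054, "N": 0.045, "D": 0.054, "C": 0.018,
    "Q": 0.035, "E": 0.067, "G": 0.064, "H": 0.023, "I": 0.053,
    "L": 0.095, "K": 0.064, "M": 0.024, "F": 0.043, "P": 0.047,
    "S": 0.090, "T": 0.051, "W": 0.012, "Y": 0.029, "V": 0.069,
}

#: one A/T-ending preferred codon per degenerate family (dicot-like)
PREFERRED_AT_ENDING: tuple[str, ...] = (
    "TTT", "TTG", "ATT", "GTT", "TCT", "CCT", "ACT", "GCT", "TAT",
    "CAT", "CAA", "AAT", "AAA", "GAT", "GAA", "TGT", "AGA", "GGT",
)

#: one G/C-ending preferred codon per degenerate family (monocot-like)
PREFERRED_GC_ENDING: tuple[str, ...] = (
    "TTC", "CTG", "ATC", "GTG", "AGC", "CCC", "ACC", "GCC", "TAC",
    "CAC", "CAG", "AAC", "AAG", "GAC", "GAG", "TGC", "AGG", "GGC",
)

#: the 61 sense codons, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

_GC = frozenset("GC")

# per-sense-codon constants for vectorized probability construction
_AA = [CODON_TO_AA[c] for c in SENSE_CODONS]
_F_AA = np.array([AA_FREQUENCIES[a] for a in _AA])
_IS_GC3 = np.array([c[2] in _GC for c in SENSE_CODONS])
_N_GC_FAM = np.array([
    sum(x[2] in _GC for x in GENETIC_CODE[a]) for a in _AA
], dtype=float)
_N_AT_FAM = np.array([len(GENETIC_CODE[a]) for a in _AA], dtype=float) - _N_GC_FAM
_DEGENERATE = np.array([len(GENETIC_CODE[a]) > 1 for a in _AA])
_PHI_GC_12 = np.array([
    sum(b in _GC for b in c[:2]) for c in SENSE_CODONS
], dtype=float)  # number of G/C among positions 1-2


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth parameters of one synthetic CDS set."""

    name: str
    n_genes: int = 2000
    length_range: tuple[int, int] = (200, 600)  # body codons (excl. start/stop)
    gc3_alpha: float = 8.0
    gc3_beta: float = 11.0
    s_sel: float = 0.0
    preferred_codons: tuple[str, ...] = ()
    high_fraction: float = 0.0
    s_sel_high: float = 0.0
    aa_mode: str = "fixed"  # "fixed" proteome or "free" (mutation-driven drift)
    stop_weights: tuple[float, float, float] = (0.35, 0.25, 0.40)  # TAA, TAG, TGA

    def __post_init__(self) -> None:
        if self.n_genes < 20:
            raise ValueError("n_genes must be >= 20")
        if self.length_range[0] < 100 or self.length_range[0] > self.length_range[1]:
            raise ValueError("gene lengths must be >= 100 codons, min <= max")
        for frac in (self.s_sel, self.high_fraction, self.s_sel_high):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.aa_mode not in ("fixed", "free"):
            raise ValueError("aa_mode must be 'fixed' or 'free'")
        for c in self.preferred_codons:
            if c not in SENSE_CODONS:
                raise ValueError(f"preferred codon {c!r} is not a sense codon")

    @property
    def gc3_mean(self) -> float:
        return self.gc3_alpha / (self.gc3_alpha + self.gc3_beta)


def _mutation_w3(g: float) -> np.ndarray:
    """Third-base weights within each family: GC mass g, AT mass 1-g."""
    w3 = np.where(
        _IS_GC3,
        g / np.maximum(_N_GC_FAM, 1.0),
        (1.0 - g) / np.maximum(_N_AT_FAM, 1.0),
    )
    return np.where(_DEGENERATE, w3, 1.0)  # Met/Trp carry their full mass


def _family_pref_mask(pref_mask: np.ndarray) -> np.ndarray:
    """Per-codon indicator that the codon's family contains a preferred codon."""
    fam_has_pref = np.zeros_like(pref_mask)
    for aa in set(_AA):
        idx = [i for i, a in enumerate(_AA) if a == aa]
        if pref_mask[idx].any():
            fam_has_pref[idx] = 1.0
    return fam_has_pref


def _codon_probabilities(
    g: float, s: float, pref_mask: np.ndarray, fam_has_pref: np.ndarray, aa_mode: str
) -> np.ndarray:
    w3 = _mutation_w3(g)
    if aa_mode == "free":
        phi12 = (g / 2.0) ** _PHI_GC_12 * ((1.0 - g) / 2.0) ** (2 - _PHI_GC_12)
        p = phi12 * w3
    else:
        # families without a preferred codon stay purely mutation-driven
        mix = (1.0 - s) * w3 + s * pref_mask
        p = _F_AA * np.where(fam_has_pref > 0, mix, w3)
    return p / p.sum()


def simulate_genes(
    scenario: SimulationScenario,
    seed: int,
    id_prefix: str = "g",
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate one synthetic CDS set plus its ground-truth table.

    Returns ``(sequences, truth)`` where ``truth`` has columns gene_id,
    gc3_equilibrium, expression_class, s_sel, n_codons.
    """
    rng = np.random.default_rng(seed)
    pref_mask = np.array([c in scenario.preferred_codons for c in SENSE_CODONS], dtype=float)
    fam_has_pref = _family_pref_mask(pref_mask)
    stop_p = np.asarray(scenario.stop_weights, dtype=float)
    stop_p = stop_p / stop_p.sum()
    stops = ("TAA", "TAG", "TGA")

    genes: list[CodingSequence] = []
    truth_rows = []
    lo, hi = scenario.length_range
    n_digits = max(4, len(str(scenario.n_genes)))
    for i in range(scenario.n_genes):
        if scenario.gc3_alpha > 0 and scenario.gc3_beta > 0:
            g = float(rng.beta(scenario.gc3_alpha, scenario.gc3_beta))
        else:
            g = scenario.gc3_mean
        g = min(max(g, 1e-3), 1.0 - 1e-3)
        is_high = rng.random() < scenario.high_fraction
        s = scenario.s_sel_high if is_high else scenario.s_sel
        length = int(rng.integers(lo, hi + 1))
        p = _codon_probabilities(g, s, pref_mask, fam_has_pref, scenario.aa_mode)
        idx = rng.choice(len(SENSE_CODONS), size=length, p=p)
        stop = stops[int(rng.choice(3, p=stop_p))]
        seq = "ATG" + "".join(SENSE_CODONS[j] for j in idx) + stop
        gene_id = f"{id_prefix}{i:0{n_digits}d}"
        genes.append(CodingSequence(gene_id, seq))
        truth_rows.append({
            "gene_id": gene_id,
            "gc3_equilibrium": g,
            "expression_class": "high" if is_high else "background",
            "s_sel": s,
            "n_codons": length + 2,
        })
    return genes, pd.DataFrame(truth_rows)


def simulate_panel(
    panel: dict[str, SimulationScenario], seed: int
) -> dict[str, tuple[list[CodingSequence], pd.DataFrame]]:
    """Simulate a multi-species panel with per-species child seeds."""
    out = {}
    children = np.random.SeedSequence(seed).spawn(len(panel))
    for child, (label, scenario) in zip(children, sorted(panel.items())):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out[label] = simulate_genes(scenario, child_seed, id_prefix=f"{label}_g")
    return out


def write_scenario_fasta(
    genes: list[CodingSequence], truth: pd.DataFrame, out_dir: str | Path, label: str
) -> tuple[Path, Path]:
    """Write a simulated set as FASTA plus its ground-truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{label}.fasta"
    tsv = out_dir / f"{label}.truth.tsv"
    write_fasta(genes, fasta)
    truth.to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def preset_scenarios() -> dict[str, SimulationScenario | dict[str, SimulationScenario]]:
    """Named study conditions with documented expected diagnostic outcomes.

    * ``mutation_only`` — no selection, free amino-acid mode: genes hug the
      expected ENC curve and the neutrality slope is near 1.
    * ``selection_dominated`` — strong preferred-codon selection with a
      fixed proteome: most genes fall below the expected ENC curve and the
      neutrality slope is near 0.
    * ``mixed`` — weak selection over mutational variation.
    * ``two_class_expression`` — a background plus a strongly biased
      high-expression class; the ENC-decile ΔRSCU procedure should recover
      the planted preferred set.
    * ``eight_species_panel`` — two clades (five dicot-like AT-preferring,
      three monocot-like GC-preferring species); RSCU clustering should
      split the clades at the root.
    """
    presets: dict[str, SimulationScenario | dict[str, SimulationScenario]] = {
        # symmetric mutation pressure: GC3 equilibrium centered on 0.5, no
        # selection; long-ish genes keep per-family sampling noise low so
        # the ENC-GC3s relation is dominated by composition, not noise
        "mutation_only": SimulationScenario(
            name="mutation_only", n_genes=2000, aa_mode="free", s_sel=0.0,
            gc3_alpha=25.0, gc3_beta=25.0, length_range=(300, 700),
        ),
        "selection_dominated": SimulationScenario(
            name="selection_dominated", n_genes=2000, s_sel=0.5,
            preferred_codons=PREFERRED_AT_ENDING,
        ),
        "mixed": SimulationScenario(
            name="mixed", n_genes=2000, s_sel=0.2,
            preferred_codons=PREFERRED_AT_ENDING,
        ),
        "two_class_expression": SimulationScenario(
            name="two_class_expression", n_genes=1000, s_sel=0.05,
            high_fraction=0.15, s_sel_high=0.7,
            preferred_codons=PREFERRED_AT_ENDING,
        ),
    }
    panel: dict[str, SimulationScenario] = {}
    for i in range(5):
        panel[f"dicot_{i + 1}"] = SimulationScenario(
            name=f"dicot_{i + 1}", n_genes=150, length_range=(150, 400),
            gc3_alpha=8.0, gc3_beta=12.0 - 0.4 * i,
            s_sel=0.20 + 0.02 * i, preferred_codons=PREFERRED_AT_ENDING,
        )
    for i in range(3):
        panel[f"monocot_{i + 1}"] = SimulationScenario(
            name=f"monocot_{i + 1}", n_genes=150, length_range=(150, 400),
            gc3_alpha=11.0 + 0.5 * i, gc3_beta=8.0,
            s_sel=0.20 + 0.02 * i, preferred_codons=PREFERRED_GC_ENDING,
        )
    presets["eight_species_panel"] = panel
    return presets
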