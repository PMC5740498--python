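"""Synthetic ground truth for the full DMS pipeline.

Generates an ORF, a mutagenized clone library with known genotypes and
true variant effects, and sequencing counts (or raw read pairs) for both
the BarSeq and TileSeq platforms, so every scoring stage can be tested
against a recoverable truth.

True variant scores follow the bimodal shape of real complementation
maps: a deleterious class concentrated near 0 (scaled Beta(0.5, 5)) and
a neutral class tightly around 1 (Normal(1, 0.05) truncated at 0).
Nonsense variants score exactly 0 and synonymous variants exactly 1.
Clone fitness is the product of its variants' true scores, clipped at 0
(the multiplicative model for intragenic combinations).

Selection dynamics: a clone with fitness f grows exponentially at the
hourly rate g(f) defined so that its cumulative population gain over
the assay interpolates linearly between the null-control and
wild-type-control gains,

    2^(g(f) * H) = (1 - f) * 2^(g_null * H) + f * 2^(g_wt * H),

with H the relevant horizon.  This makes the noise-free scoring chain
an identity on true scores, so parameter-recovery tests measure the
noise behaviour of the pipeline rather than an arbitrary link function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .barseq import (
    PERMISSIVE, SELECTIVE, BarcodeLibrary, BarSeqCounts, CloneRecord,
)
from .popcode import nnk_table
from .seqcore import (
    AA_ALPHABET, STOP, CodonVariant, OrfSequence, STANDARD_CODE, translate,
)
from .tileseq import (
    CONDITIONS, NONSELECT, SELECT, WTCTRL, CodonCountTable, TileDefinition,
    make_tiles,
)

__all__ = [
    "SimConfig",
    "multi_mutant_fraction",
    "random_orf",
    "simulate_truth",
    "simulate_library",
    "simulate_barseq",
    "simulate_tileseq",
    "tile_read_pairs",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic screens.

    L
        protein length in residues (ORF has L + 1 codons with the stop).
    n_clones
        clones in the mutagenized pool.
    lam
        mean amino-acid changes per clone (Poisson).
    lam_syn
        mean additional synonymous codon changes per clone — NNK
        replacement draws land on a synonymous codon a few percent of
        the time.
    p_del
        fraction of missense variants that are deleterious.
    g_wt, g_null
        doublings per hour at the selective temperature for wild-type
        and null clones (ts allele nearly dead).
    timepoints_h
        BarSeq sampling times; growth runs to the last timepoint.
    barseq_depth / tileseq_depth
        reads per BarSeq sample / per tile and condition replicate.
    base_error
        per-base, per-mate sequencing error rate.
    template_error
        per-base template (PCR/plasmid) error rate, shared by both
        mates and not removable by two-strand agreement.
    od_noise
        lognormal sigma on pool-size (OD) estimates.
    """

    L: int = 50
    n_clones: int = 20_000
    lam: float = 2.1
    lam_syn: float = 0.15
    p_del: float = 0.4
    del_beta: tuple[float, float] = (0.5, 5.0)
    neutral_sd: float = 0.05
    g_wt: float = 0.42
    g_null: float = 0.04
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    n_replicates: int = 3
    n_wt_controls: int = 25
    n_null_controls: int = 25
    barseq_depth: int = 1_000_000
    tileseq_depth: int = 2_000_000
    tileseq_select_h: float = 24.0
    base_error: float = 0.001
    template_error: float = 1e-5
    od_noise: float = 0.05
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.g_null < self.g_wt:
            raise ValueError("need 0 < g_null < g_wt")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.barseq_depth <= 0 or self.tileseq_depth <= 0:
            raise ValueError("depths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("timepoints_h", "del_beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["timepoints_h"] = list(self.timepoints_h)
        d["del_beta"] = list(self.del_beta)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def multi_mutant_fraction(lam: float) -> float:
    """Poisson probability of more than one amino-acid change per clone."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return float(1.0 - np.exp(-lam) - lam * np.exp(-lam))


def _growth_gain(fitness: np.ndarray, g_null: float, g_wt: float,
                 horizon: float) -> np.ndarray:
    """Cumulative population gain 2^(g(f)*horizon), linear in fitness.

    ``horizon`` is the exponent scale on which the linear anchoring
    holds: selection hours for TileSeq, the number of scored intervals
    for the BarSeq cumulative score.
    """
    f = np.clip(np.asarray(fitness, dtype=float), 0.0, None)
    return (1.0 - f) * 2.0 ** (g_null * horizon) + f * 2.0 ** (g_wt * horizon)


def random_orf(L: int, rng: np.random.Generator, id: str = "synthetic_orf"
               ) -> OrfSequence:
    """Random ORF of L sense codons (ATG start) plus a TAA stop."""
    sense = [c for c in STANDARD_CODE.codons if STANDARD_CODE[c] != STOP]
    body = rng.choice(sense, size=L - 1)
    return OrfSequence(id, "ATG" + "".join(body) + "TAA")


def simulate_truth(orf: OrfSequence, cfg: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """True score per possible amino-acid variant at positions 2..L.

    Returns a table keyed like the score maps (position, wt_aa, mut_aa)
    with columns ``true_score`` and ``class``.
    """
    protein = translate(orf)
    rows = []
    a, b = cfg.del_beta
    for pos in range(2, len(protein) + 1):
        wt = protein[pos - 1]
        for mut in AA_ALPHABET + STOP:
            if mut == wt:
                continue
            if mut == STOP:
                cls, score = "nonsense", 0.0
            else:
                cls = "missense"
                if rng.random() < cfg.p_del:
                    score = float(rng.beta(a, b))
                else:
                    score = max(0.0, float(rng.normal(1.0, cfg.neutral_sd)))
            rows.append(
                {"position": pos, "wt_aa": wt, "mut_aa": mut,
                 "key": f"{wt}{pos}{mut}", "true_score": score, "class": cls}
            )
    return pd.DataFrame(rows)


def _nnk_codon_groups(wt_codon: str) -> tuple[list[str], list[str]]:
    """NNK codons at a position, split into (non-synonymous, synonymous)."""
    wt_aa = STANDARD_CODE[wt_codon]
    table = nnk_table()
    nonsyn = [c for c, aa in zip(table.codon, table.aa)
              if aa != wt_aa]
    syn = [c for c, aa in zip(table.codon, table.aa)
           if aa == wt_aa and c != wt_codon]
    return nonsyn, syn


def simulate_library(
    cfg: SimConfig,
    mode: str = "tileseq",
    rng: np.random.Generator | None = None,
    truncate: bool | None = None,
) -> tuple[OrfSequence, pd.DataFrame, pd.DataFrame]:
    """Generate the ORF, truth table and mutagenized clone pool.

    Per clone, the amino-acid change count is Poisson(lam) (truncated to
    >= 1 in BarSeq mode, where only clones with at least one substitution
    are retained in the arrayed library), target codons are uniform over
    positions 2..L, and mutant codons are drawn uniformly from the
    non-synonymous NNK codons at the position; Poisson(lam_syn) extra
    synonymous NNK changes model the synonymous draws of NNK replacement.

    Returns (orf, clone table, truth table).  The clone table has
    columns clone_id, genotype (;-joined codon variants), aa_changes
    (;-joined compact aa variants), n_aa_changes, fitness.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if truncate is None:
        truncate = mode == "barseq"
    orf = random_orf(cfg.L, rng)
    truth = simulate_truth(orf, cfg, rng)
    true_score = dict(zip(truth.key, truth.true_score))

    positions = np.arange(2, cfg.L + 1)
    nonsyn_by_pos: dict[int, list[str]] = {}
    syn_by_pos: dict[int, list[str]] = {}
    for pos in positions:
        nonsyn_by_pos[pos], syn_by_pos[pos] = _nnk_codon_groups(orf.codon(pos))

    n_changes = rng.poisson(cfg.lam, size=cfg.n_clones)
    if truncate:
        while (n_changes == 0).any():
            zero = n_changes == 0
            n_changes[zero] = rng.poisson(cfg.lam, size=int(zero.sum()))
    n_syn = rng.poisson(cfg.lam_syn, size=cfg.n_clones)

    rows = []
    for i in range(cfg.n_clones):
        k = min(int(n_changes[i]), len(positions))
        k_syn = int(n_syn[i])
        n_pick = min(k + k_syn, len(positions))
        picked = rng.choice(positions, size=n_pick, replace=False)
        aa_pos, syn_pos = picked[:k], picked[k:]
        genotype, aa_strs = [], []
        fitness = 1.0
        for pos in aa_pos:
            wt_codon = orf.codon(int(pos))
            mut_codon = str(rng.choice(nonsyn_by_pos[int(pos)]))
            v = CodonVariant(int(pos), wt_codon, mut_codon)
            genotype.append(v)
            aa = v.aa_variant()
            aa_strs.append(str(aa))
            fitness *= 0.0 if aa.is_nonsense else true_score[
                f"{aa.wt_aa}{aa.position}{aa.mut_aa}"
            ]
        for pos in syn_pos:
            syn_codons = syn_by_pos[int(pos)]
            if not syn_codons:
                continue
            genotype.append(
                CodonVariant(int(pos), orf.codon(int(pos)),
                             str(rng.choice(syn_codons)))
            )
        rows.append(
            {
                "clone_id": f"clone{i:06d}",
                "genotype": ";".join(str(v) for v in genotype),
                "aa_changes": ";".join(aa_strs),
                "n_aa_changes": len(aa_strs),
                "fitness": max(fitness, 0.0),
            }
        )
    return orf, pd.DataFrame(rows), truth


def clone_pool_to_barcode_library(
    pool: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> BarcodeLibrary:
    """Attach unique random 25-nt barcodes; add null and wt controls."""
    entries: dict[str, CloneRecord] = {}

    def fresh_barcode() -> str:
        while True:
            bc = "".join(rng.choice(list("ACGT"), size=25))
            if bc not in entries:
                return bc

    for row in pool.itertuples(index=False):
        genotype = tuple(
            CodonVariant.from_string(s) for s in row.genotype.split(";") if s
        )
        entries[fresh_barcode()] = CloneRecord(row.clone_id, genotype, "variant")
    for j in range(cfg.n_null_controls):
        entries[fresh_barcode()] = CloneRecord(f"null{j:03d}", (), "null_control")
    for j in range(cfg.n_wt_controls):
        entries[fresh_barcode()] = CloneRecord(f"wt{j:03d}", (), "wt_control")
    return BarcodeLibrary(entries)


def simulate_barseq(
    cfg: SimConfig,
    library: BarcodeLibrary,
    pool: pd.DataFrame,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> BarSeqCounts:
    """Competition time series with multinomial sequencing counts.

    Clone populations grow exponentially; the fitness-to-rate map
    anchors the cumulative selective gain linearly between the null and
    wild-type controls (module docstring).  At the permissive
    temperature every clone grows at the wild-type rate.  Counts are
    multinomial draws of ``barseq_depth`` reads per sample and pool
    sizes carry lognormal OD noise.  With ``exact=True`` counts equal
    scaled true proportions and OD noise is off (deterministic limit).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    fitness = dict(zip(pool.clone_id, pool.fitness))
    clone_ids = [r.clone_id for r in library.clones]
    f = np.array(
        [
            1.0 if library.clone(c).control_class == "wt_control"
            else 0.0 if library.clone(c).control_class == "null_control"
            else fitness[c]
            for c in clone_ids
        ]
    )
    tps = list(cfg.timepoints_h)
    # the cumulative score multiplies one hourly-rate ratio per interval,
    # so the linear fitness anchoring lives on the K-interval scale
    K = len(tps) - 1
    mK = _growth_gain(f, cfg.g_null, cfg.g_wt, K)
    p0 = 1000.0

    counts_cols, pool_sizes = {}, {}
    for tau, rep in itertools.product((PERMISSIVE, SELECTIVE),
                                      range(1, cfg.n_replicates + 1)):
        for t in tps:
            if tau == PERMISSIVE:
                P = np.full(len(f), p0 * 2.0 ** (cfg.g_wt * t))
            else:
                P = p0 * mK ** (t / K)
            total = P.sum()
            share = P / total
            if exact:
                counts_cols[(t, tau, rep)] = share * 1e12
                pool_sizes[(t, tau, rep)] = total
            else:
                counts_cols[(t, tau, rep)] = rng.multinomial(
                    cfg.barseq_depth, share
                )
                pool_sizes[(t, tau, rep)] = total * float(
                    rng.lognormal(0.0, cfg.od_noise)
                )
    counts = pd.DataFrame(
        counts_cols, index=pd.Index(clone_ids, name="clone_id")
    )
    counts.columns = pd.MultiIndex.from_tuples(
        counts.columns, names=["timepoint_h", "temperature", "replicate"]
    )
    psize = pd.Series(pool_sizes)
    psize.index = pd.MultiIndex.from_tuples(
        psize.index, names=["timepoint_h", "temperature", "replicate"]
    )
    return BarSeqCounts(counts, psize)


# ---------------------------------------------------------------------------
# TileSeq
# ---------------------------------------------------------------------------

def _single_nt_neighbors(codon: str) -> list[str]:
    out = []
    for i in range(3):
        for nt in "ACGT":
            if nt != codon[i]:
                out.append(codon[:i] + nt + codon[i + 1 :])
    return out


def simulate_tileseq(
    cfg: SimConfig,
    pool: pd.DataFrame,
    orf: OrfSequence,
    rng: np.random.Generator | None = None,
) -> CodonCountTable:
    """Codon-change counts for nonselect/select/wtctrl conditions.

    Clone abundances carry mild lognormal variation; selection reweights
    each clone by its cumulative growth gain over ``tileseq_select_h``
    hours.  Error background per specific single-nucleotide codon
    change: template errors at rate template_error/3 (present in every
    condition including the wild-type control) plus the residual
    both-strand sequencing error (base_error/3)^2.  Counts are binomial
    draws at ``tileseq_depth`` per codon position.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    abundance = rng.lognormal(0.0, 0.3, size=len(pool))
    gain = _growth_gain(
        pool.fitness.to_numpy(), cfg.g_null, cfg.g_wt, cfg.tileseq_select_h
    )
    w_ns = abundance / abundance.sum()
    w_sel = abundance * gain
    w_sel = w_sel / w_sel.sum()

    # aggregate per-codon-variant pool frequencies
    freq_ns: dict[tuple[int, str, str], float] = {}
    freq_sel: dict[tuple[int, str, str], float] = {}
    for i, genotype in enumerate(pool.genotype):
        if not genotype:
            continue
        for s in genotype.split(";"):
            v = CodonVariant.from_string(s)
            k = (v.codon_index, v.wt_codon, v.mut_codon)
            freq_ns[k] = freq_ns.get(k, 0.0) + w_ns[i]
            freq_sel[k] = freq_sel.get(k, 0.0) + w_sel[i]

    # error background on every single-nt neighbor of the wt codons
    p_template = cfg.template_error / 3.0
    p_seq = (cfg.base_error / 3.0) ** 2
    background: dict[tuple[int, str, str], float] = {}
    for pos in range(2, cfg.L + 1):
        wt = orf.codon(pos)
        for mut in _single_nt_neighbors(wt):
            background[(pos, wt, mut)] = p_template + p_seq

    variants = sorted(set(freq_ns) | set(background))
    count_rows, depth_rows = [], []
    depth = cfg.tileseq_depth
    for cond in CONDITIONS:
        for rep in (1, 2):
            for k in variants:
                bg = background.get(k, p_seq)
                if cond == NONSELECT:
                    p = freq_ns.get(k, 0.0) + bg
                elif cond == SELECT:
                    p = freq_sel.get(k, 0.0) + bg
                else:
                    p = bg
                c = int(rng.binomial(depth, min(p, 1.0)))
                if c > 0:
                    count_rows.append(
                        {
                            "codon_index": k[0], "wt_codon": k[1],
                            "mut_codon": k[2], "condition": cond,
                            "replicate": rep, "count": c,
                        }
                    )
            for pos in range(2, cfg.L + 1):
                depth_rows.append(
                    {"codon_index": pos, "condition": cond,
                     "replicate": rep, "depth": depth}
                )
    return CodonCountTable(pd.DataFrame(count_rows), pd.DataFrame(depth_rows))


def tile_read_pairs(
    orf: OrfSequence,
    tile: TileDefinition,
    genotypes: Sequence[str],
    weights: np.ndarray | None,
    n_pairs: int,
    base_error: float,
    template_error: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Paired full-tile reads from a weighted template population.

    ``genotypes`` are ;-joined codon-variant strings (empty for wild
    type); one template is drawn per pair, template errors (shared by
    both mates) are applied, then each mate is corrupted independently
    at ``base_error`` per base.
    """
    ref = np.frombuffer(tile.reference(orf).encode(), dtype=np.uint8)
    L = len(ref)
    choice = rng.choice(len(genotypes), size=n_pairs, p=weights)
    templates = np.tile(ref, (n_pairs, 1))

    # apply clone genotypes that fall within the tile
    edits: dict[int, list[tuple[int, np.ndarray]]] = {}
    for gi, g in enumerate(genotypes):
        if not g:
            continue
        lst = []
        for s in g.split(";"):
            v = CodonVariant.from_string(s)
            if tile.first_codon <= v.codon_index <= tile.last_codon:
                off = 3 * (v.codon_index - tile.first_codon)
                lst.append((off, np.frombuffer(v.mut_codon.encode(), dtype=np.uint8)))
        if lst:
            edits[gi] = lst
    for gi, lst in edits.items():
        idx = np.nonzero(choice == gi)[0]
        for off, codon in lst:
            templates[idx, off : off + 3] = codon

    def corrupt(arr: np.ndarray, rate: float) -> np.ndarray:
        if rate <= 0:
            return arr
        mask = rng.random(arr.shape) < rate
        n_err = int(mask.sum())
        if n_err:
            # substitute with a uniformly chosen different base
            shift = rng.integers(1, 4, size=n_err)
            cur = np.searchsorted(_BASES, arr[mask])
            arr = arr.copy()
            arr[mask] = _BASES[(cur + shift) % 4]
        return arr

    templates = corrupt(templates, template_error)
    m1 = corrupt(templates, base_error)
    m2 = corrupt(templates, base_error)
    to_str = lambda a: [bytes(row).decode() for row in a]
    return to_str(m1), to_str(m2)


def simulate_tileseq_reads(
    cfg: SimConfig,
    pool: pd.DataFrame | None,
    orf: OrfSequence,
    tiles: Sequence[TileDefinition] | None = None,
    condition: str = NONSELECT,
    n_pairs_per_tile: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[list[str], list[str]]]:
    """Read pairs per tile for one condition (wtctrl if pool is None)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    if tiles is None:
        tiles = make_tiles(orf)
    if pool is None or condition == WTCTRL:
        genotypes, weights = [""], None
    else:
        genotypes = list(pool.genotype)
        abundance = np.ones(len(pool))
        if condition == SELECT:
            abundance = _growth_gain(
                pool.fitness.to_numpy(), cfg.g_null, cfg.g_wt,
                cfg.tileseq_select_h,
            )
        weights = abundance / abundance.sum()
    return {
        t.tile_id: tile_read_pairs(
            orf, t, genotypes, weights, n_pairs_per_tile,
            cfg.base_error, cfg.template_error, rng,
        )
        for t in tiles
    }


def write_fastq(reads: Sequence[str], path: str | Path,
                prefix: str = "read") -> None:
    """Minimal FASTQ writer with uniform quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
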