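"""TileSeq codon-variant counting and enrichment-ratio scoring.

TileSeq quantifies variant allele frequencies in a mutagenized clone
pool by deep paired-end sequencing of short amplicon tiles covering the
ORF.  Because every template molecule is read on both strands, a codon
change is only counted when both mates of a pair report the identical
mutant codon, which suppresses base-calling errors quadratically.

Scoring chain per codon variant v:

    freq[cond, rep]  = count / depth at the variant's codon
    (filter)           variants whose input frequency is within three
                       standard deviations of the wild-type-control
                       frequency are considered poorly measured
    adj[cond]        = freq[cond] - freq[wtctrl]   (floored at eps > 0)
    E[rep]           = adj_select / adj_nonselect
    score            = (E - median_nonsense) / (median_syn - median_nonsense)

so that nonsense variants center on 0 and synonymous variants on 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqcore import CodonVariant, OrfSequence, classify_codon_variant

__all__ = [
    "TileDefinition",
    "make_tiles",
    "CodonCountTable",
    "call_codon_changes",
    "filter_low_input",
    "tileseq_score",
    "anchor_scores",
    "TileSeqModel",
    "TileSeqResults",
]

NONSELECT = "nonselect"
SELECT = "select"
WTCTRL = "wtctrl"
CONDITIONS = (NONSELECT, SELECT, WTCTRL)

_BASE_TO_INT = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class TileDefinition:
    """An amplicon tile spanning an inclusive 1-based codon interval."""

    tile_id: str
    first_codon: int
    last_codon: int

    def __post_init__(self) -> None:
        if self.first_codon < 1 or self.last_codon < self.first_codon:
            raise ValueError("invalid codon interval")

    @property
    def n_codons(self) -> int:
        return self.last_codon - self.first_codon + 1

    @property
    def nt_span(self) -> int:
        return 3 * self.n_codons

    def reference(self, orf: OrfSequence) -> str:
        start = (self.first_codon - 1) * 3
        return orf.nucleotides[start : start + self.nt_span]


def make_tiles(orf: OrfSequence, max_span_nt: int = 150) -> list[TileDefinition]:
    """Partition the mutagenized codons (2..L) into non-overlapping tiles."""
    per_tile = max_span_nt // 3
    codons = list(range(2, orf.n_codons))  # skip Met1 and stop
    tiles = []
    for i in range(0, len(codons), per_tile):
        chunk = codons[i : i + per_tile]
        tiles.append(TileDefinition(f"tile{len(tiles) + 1}", chunk[0], chunk[-1]))
    return tiles


@dataclass
class CodonCountTable:
    """Codon-change counts and positional depths per condition/replicate.

    ``counts``: columns (codon_index, wt_codon, mut_codon, condition,
    replicate, count).  ``depths``: columns (codon_index, condition,
    replicate, depth).
    """

    counts: pd.DataFrame
    depths: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("codon_index", "wt_codon", "mut_codon", "condition",
                    "replicate", "count"):
            if col not in self.counts.columns:
                raise ValueError(f"counts missing column {col}")
        for col in ("codon_index", "condition", "replicate", "depth"):
            if col not in self.depths.columns:
                raise ValueError(f"depths missing column {col}")
        bad = set(self.counts["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {bad}")

    def replicates(self, condition: str) -> list:
        return sorted(
            self.depths.loc[self.depths.condition == condition, "replicate"].unique()
        )

    def depth_lookup(self) -> pd.Series:
        return self.depths.set_index(["codon_index", "condition", "replicate"])[
            "depth"
        ]

    def to_tsv(self, path: str | Path) -> None:
        counts = self.counts.copy()
        counts["kind"] = "count"
        depths = self.depths.copy()
        depths["kind"] = "depth"
        pd.concat([counts, depths]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonCountTable":
        df = pd.read_csv(path, sep="\t")
        counts = df[df.kind == "count"].drop(columns=["kind", "depth"], errors="ignore")
        depths = df[df.kind == "depth"][
            ["codon_index", "condition", "replicate", "depth"]
        ]
        depths["depth"] = depths["depth"].astype(int)
        counts["count"] = counts["count"].astype(int)
        return cls(counts.reset_index(drop=True), depths.reset_index(drop=True))


# ---------------------------------------------------------------------------
# read-pair counting
# ---------------------------------------------------------------------------

def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Byte-encode equal-length sequences into a (n, L) uint8 array."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def count_tile_pairs(
    mate1: Sequence[str],
    mate2: Sequence[str],
    tile: TileDefinition,
    orf: OrfSequence,
    require_both_mates: bool = True,
    max_mismatch_frac: float = 0.10,
) -> tuple[dict[CodonVariant, int], int]:
    """Count codon changes in full-tile read pairs against the reference.

    Reads are compared to the tile reference at fixed coordinates
    (amplicons have known positions; no alignment is performed).  Pairs
    with length mismatches or more than ``max_mismatch_frac`` mismatched
    bases in either mate are discarded.  With ``require_both_mates`` a
    codon change is counted only when both mates carry the identical
    mutant codon; otherwise mate1 alone is used (error-prone, for
    comparison only).

    Returns (variant counts, number of retained pairs = positional depth).
    """
    if len(mate1) != len(mate2):
        raise ValueError("mate lists differ in length")
    if not mate1:
        return {}, 0
    ref = tile.reference(orf)
    L = len(ref)
    if any(len(s) != L for s in mate1) or any(len(s) != L for s in mate2):
        raise ValueError("reads must cover the full tile")

    a1 = _encode(mate1)
    a2 = _encode(mate2)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    mm1 = a1 != ref_arr
    mm2 = a2 != ref_arr
    keep = (mm1.mean(axis=1) <= max_mismatch_frac) & (
        mm2.mean(axis=1) <= max_mismatch_frac
    )
    a1, a2, mm1, mm2 = a1[keep], a2[keep], mm1[keep], mm2[keep]
    depth = int(keep.sum())

    n_codons = L // 3
    mm1c = mm1.reshape(-1, n_codons, 3).any(axis=2)
    if require_both_mates:
        agree = (a1 == a2).reshape(-1, n_codons, 3).all(axis=2)
        called = mm1c & mm2.reshape(-1, n_codons, 3).any(axis=2) & agree
    else:
        called = mm1c

    counts: dict[CodonVariant, int] = {}
    pair_idx, codon_idx = np.nonzero(called)
    for p, c in zip(pair_idx, codon_idx):
        mut = bytes(a1[p, 3 * c : 3 * c + 3]).decode()
        wt = ref[3 * c : 3 * c + 3]
        v = CodonVariant(tile.first_codon + int(c), wt, mut)
        counts[v] = counts.get(v, 0) + 1
    return counts, depth


def _read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def call_codon_changes(
    pairs: dict[str, tuple[Sequence[str], Sequence[str]]]
    | tuple[str | Path, str | Path],
    orf: OrfSequence,
    tiles: Sequence[TileDefinition],
    condition: str = NONSELECT,
    replicate: int = 1,
    require_both_mates: bool = True,
) -> CodonCountTable:
    """Build a codon-count table for one condition/replicate.

    ``pairs`` maps tile_id -> (mate1 reads, mate2 reads); alternatively a
    (fastq1, fastq2) path pair may be given, in which case reads are
    assigned to the tile whose length matches (each read must span its
    full tile).
    """
    tile_by_id = {t.tile_id: t for t in tiles}
    if isinstance(pairs, tuple):
        m1, m2 = _read_fastq(pairs[0]), _read_fastq(pairs[1])
        if len(m1) != len(m2):
            raise ValueError("mate FASTQ files differ in read count")
        by_len = {}
        for t in tiles:
            if t.nt_span in by_len:
                raise ValueError(
                    "tiles share a span length; pass reads per tile instead"
                )
            by_len[t.nt_span] = t
        grouped: dict[str, tuple[list[str], list[str]]] = {
            t.tile_id: ([], []) for t in tiles
        }
        for r1, r2 in zip(m1, m2):
            t = by_len.get(len(r1))
            if t is None:
                raise ValueError(f"no tile of span {len(r1)} nt")
            grouped[t.tile_id][0].append(r1)
            grouped[t.tile_id][1].append(r2)
        pairs = grouped

    count_rows, depth_rows = [], []
    for tile_id, (m1, m2) in pairs.items():
        tile = tile_by_id.get(tile_id)
        if tile is None:
            raise ValueError(f"unknown tile {tile_id}")
        counts, depth = count_tile_pairs(
            m1, m2, tile, orf, require_both_mates=require_both_mates
        )
        for v, n in counts.items():
            count_rows.append(
                {
                    "codon_index": v.codon_index,
                    "wt_codon": v.wt_codon,
                    "mut_codon": v.mut_codon,
                    "condition": condition,
                    "replicate": replicate,
                    "count": n,
                }
            )
        for ci in range(tile.first_codon, tile.last_codon + 1):
            depth_rows.append(
                {
                    "codon_index": ci,
                    "condition": condition,
                    "replicate": replicate,
                    "depth": depth,
                }
            )
    return CodonCountTable(
        pd.DataFrame(
            count_rows,
            columns=["codon_index", "wt_codon", "mut_codon", "condition",
                     "replicate", "count"],
        ),
        pd.DataFrame(
            depth_rows, columns=["codon_index", "condition", "replicate", "depth"]
        ),
    )


def merge_count_tables(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    tables = list(tables)
    return CodonCountTable(
        pd.concat([t.counts for t in tables], ignore_index=True),
        pd.concat([t.depths for t in tables], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# frequencies, filtering, scoring
# ---------------------------------------------------------------------------

def _frequency_frame(table: CodonCountTable) -> pd.DataFrame:
    """Wide per-variant frequency table with one column per (cond, rep).

    Variants absent from a condition's counts get frequency 0 (their
    depth is still defined by the positional depth track).
    """
    depth = table.depth_lookup()
    variants = (
        table.counts[["codon_index", "wt_codon", "mut_codon"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    key = table.counts.set_index(
        ["codon_index", "wt_codon", "mut_codon", "condition", "replicate"]
    )["count"]
    out = variants.copy()
    for cond in CONDITIONS:
        for rep in table.replicates(cond):
            idx = pd.MultiIndex.from_arrays(
                [
                    variants.codon_index,
                    [cond] * len(variants),
                    [rep] * len(variants),
                ]
            )
            d = depth.reindex(idx).to_numpy(dtype=float)
            full_key = pd.MultiIndex.from_arrays(
                [
                    variants.codon_index,
                    variants.wt_codon,
                    variants.mut_codon,
                    [cond] * len(variants),
                    [rep] * len(variants),
                ]
            )
            c = key.reindex(full_key).fillna(0.0).to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[(cond, rep)] = np.where(d > 0, c / d, np.nan)
            out[("count", cond, rep)] = c
            out[("depth", cond, rep)] = d
    return out


def _wtctrl_stats(freq: pd.DataFrame, reps: list) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sd of wild-type-control frequencies per variant.

    The across-replicate sd is floored at the Poisson expectation
    sqrt(mean count) / depth, which stabilizes the two-replicate sd.
    """
    cols = [(WTCTRL, r) for r in reps]
    f = freq[cols].to_numpy(dtype=float)
    mean = np.nanmean(f, axis=1)
    sd = np.nanstd(f, axis=1, ddof=1) if len(reps) > 1 else np.zeros(len(f))
    counts = freq[[("count", WTCTRL, r) for r in reps]].to_numpy(dtype=float)
    depths = freq[[("depth", WTCTRL, r) for r in reps]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        poisson = np.sqrt(np.maximum(counts.mean(axis=1), 1.0)) / np.nanmean(
            depths, axis=1
        )
    return mean, np.maximum(np.nan_to_num(sd), poisson)


def filter_low_input(
    input_freq: np.ndarray,
    wt_mean: np.ndarray,
    wt_sd: np.ndarray,
) -> np.ndarray:
    """Keep mask: input frequency must exceed wtctrl mean + 3 sd.

    Variants whose pre-selection frequency is within three standard
    deviations of the sequencing-error background cannot support
    confident detection of post-selection depletion.
    """
    return np.asarray(input_freq) > np.asarray(wt_mean) + 3.0 * np.asarray(wt_sd)


class TileSeqModel:
    """Enrichment-ratio scoring of a TileSeq codon-count table.

    Parameters
    ----------
    table
        codon-change counts and positional depths for the nonselect,
        select and wtctrl conditions (>= 2 replicates each).
    filter_on
        condition whose frequency is tested against the wild-type
        control background.  The default, ``nonselect``, reads the
        poorly-measured filter as an input-frequency requirement — the
        rationale being confident detection of post-selection reduction;
        ``select`` applies the literal post-selection reading.
    """

    def __init__(
        self,
        table: CodonCountTable,
        gene: str = "GENE",
        filter_on: str = NONSELECT,
    ):
        if filter_on not in (NONSELECT, SELECT):
            raise ValueError("filter_on must be nonselect or select")
        for cond in CONDITIONS:
            if len(table.replicates(cond)) < 2:
                raise ValueError(f"condition {cond} needs >= 2 replicates")
        self.table = table
        self.gene = gene
        self.filter_on = filter_on

    def fit(self) -> "TileSeqResults":
        scores = tileseq_score(self.table, filter_on=self.filter_on)
        return TileSeqResults(self, scores)


def tileseq_score(
    table: CodonCountTable, filter_on: str = NONSELECT
) -> pd.DataFrame:
    """Per-codon-variant enrichment ratios with filtering.

    Adjusted frequencies are wtctrl-subtracted and floored at
    eps = 1 / (10 * max depth) so that fully depleted variants keep a
    finite, near-zero enrichment ratio.
    """
    freq = _frequency_frame(table)
    ns_reps = table.replicates(NONSELECT)
    sel_reps = table.replicates(SELECT)
    wt_reps = table.replicates(WTCTRL)

    wt_mean, wt_sd = _wtctrl_stats(freq, wt_reps)
    eps = 1.0 / (10.0 * float(table.depths["depth"].max()))

    filt_cols = [(filter_on, r) for r in table.replicates(filter_on)]
    filt_freq = np.nanmean(freq[filt_cols].to_numpy(dtype=float), axis=1)
    keep = filter_low_input(filt_freq, wt_mean, wt_sd)

    # pair replicates positionally (rep1 with rep1 etc.)
    n_pairs = min(len(ns_reps), len(sel_reps))
    E = np.full((len(freq), n_pairs), np.nan)
    unscorable = np.zeros(len(freq), dtype=bool)
    for j in range(n_pairs):
        f_ns = freq[(NONSELECT, ns_reps[j])].to_numpy(dtype=float)
        f_sel = freq[(SELECT, sel_reps[j])].to_numpy(dtype=float)
        adj_ns = f_ns - wt_mean
        adj_sel = np.maximum(f_sel - wt_mean, eps)
        bad = adj_ns <= eps
        unscorable |= bad & keep
        adj_ns = np.maximum(adj_ns, eps)
        E[:, j] = adj_sel / adj_ns

    out = freq[["codon_index", "wt_codon", "mut_codon"]].copy()
    out["gene"] = ""
    out["E"] = np.nanmean(E, axis=1)
    out["sd"] = np.nanstd(E, axis=1, ddof=1)
    out["df"] = n_pairs
    out["se"] = out["sd"] / np.sqrt(n_pairs)
    out["filtered"] = ~keep | unscorable
    out["reason"] = np.select(
        [~keep, unscorable], ["low_input", "unscorable"], default=""
    )
    out.loc[out.filtered, ["E", "sd", "se"]] = np.nan
    out["class"] = [
        classify_codon_variant(CodonVariant(r.codon_index, r.wt_codon, r.mut_codon))
        for r in out.itertuples(index=False)
    ]
    return out


def anchor_scores(scores: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Rescale enrichment ratios to the nonsense/synonymous anchor scale.

    score = (E - median(nonsense)) / (median(synonymous) - median(nonsense))

    so the nonsense median maps to exactly 0 and the synonymous median
    to exactly 1; sd and se scale by the same factor.
    """
    ok = ~scores["filtered"]
    med_non = scores.loc[ok & (scores["class"] == "nonsense"), "E"].median()
    med_syn = scores.loc[ok & (scores["class"] == "synonymous"), "E"].median()
    n_non = int((ok & (scores["class"] == "nonsense")).sum())
    n_syn = int((ok & (scores["class"] == "synonymous")).sum())
    if n_non < 5 or n_syn < 5:
        raise ValueError(
            f"need >= 5 scored nonsense and synonymous variants "
            f"(have {n_non}, {n_syn})"
        )
    if med_syn == med_non:
        raise ValueError("anchor medians coincide; no dynamic range")
    scale = med_syn - med_non
    out = scores.copy()
    out["score"] = (out["E"] - med_non) / scale
    out["sd"] = out["sd"] / abs(scale)
    out["se"] = out["se"] / abs(scale)
    return out, {"median_nonsense": med_non, "median_synonymous": med_syn}


class TileSeqResults:
    """Scored TileSeq table with anchoring and amino-acid aggregation."""

    def __init__(self, model: TileSeqModel, codon_scores: pd.DataFrame):
        self.model = model
        self.codon_scores = codon_scores
        self._anchored, self.anchors = anchor_scores(codon_scores)

    @property
    def anchored(self) -> pd.DataFrame:
        return self._anchored

    def score_map(self) -> pd.DataFrame:
        """Anchored scores aggregated to amino-acid variants.

        Codon variants producing the same amino-acid change are combined
        by inverse-variance weighting (missense and nonsense retained;
        synonymous/stop rows excluded from the map).
        """
        df = self._anchored[~self._anchored.filtered].copy()
        df = df[df["class"].isin(["missense", "nonsense"])]
        df["position"] = df["codon_index"]
        df["wt_aa"] = [
            CodonVariant(r.codon_index, r.wt_codon, r.mut_codon).wt_aa
            for r in df.itertuples(index=False)
        ]
        df["mut_aa"] = [
            CodonVariant(r.codon_index, r.wt_codon, r.mut_codon).mut_aa
            for r in df.itertuples(index=False)
        ]
        rows = []
        for (pos, wt, mut), grp in df.groupby(["position", "wt_aa", "mut_aa"]):
            se = grp["se"].replace(0.0, grp["se"][grp["se"] > 0].min() or 1e-6)
            se = se.fillna(se.max() if se.notna().any() else 1.0)
            w = 1.0 / se**2
            rows.append(
                {
                    "gene": self.model.gene,
                    "position": int(pos),
                    "wt_aa": wt,
                    "mut_aa": mut,
                    "score": float((w * grp["score"]).sum() / w.sum()),
                    "sd": float(np.sqrt((w * grp["sd"] ** 2).sum() / w.sum())),
                    "se": float(np.sqrt(1.0 / w.sum())),
                    "df": int(grp["df"].sum()),
                    "provenance": "measured",
                }
            )
        return pd.DataFrame(rows).sort_values(["position", "mut_aa"]).reset_index(
            drop=True
        )

    def summary(self) -> str:
        cs = self.codon_scores
        a = self.anchored
        ok = ~a.filtered
        lines = [
            "TileSeq enrichment results",
            "=" * 38,
            f"codon variants          {len(cs):>8d}",
            f"filtered (low input)    {(cs.reason == 'low_input').sum():>8d}",
            f"unscorable              {(cs.reason == 'unscorable').sum():>8d}",
            f"nonsense median E       {self.anchors['median_nonsense']:>8.4f}",
            f"synonymous median E     {self.anchors['median_synonymous']:>8.4f}",
            f"anchored syn median     {a.loc[ok & (a['class'] == 'synonymous'), 'score'].median():>8.4f}",
            f"anchored nonsense median{a.loc[ok & (a['class'] == 'nonsense'), 'score'].median():>8.4f}",
        ]
        return "\n".join(lines)
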