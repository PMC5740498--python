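"""BarSeq fitness scoring for pooled complementation screens.

A pool of barcoded clones competes at a permissive and a selective
temperature; plasmid barcodes are sequenced at several timepoints.  Each
clone's growth is compared to the pool average, cumulatively across
timepoints, and calibrated against internal null and wild-type controls
so that null-like clones score 0 and wild-type-like clones score 1.

For clone i at timepoint t_k and temperature tau, with barcode count
c and pool cell count P*:

    r_{i,tk}   = c_{i,tk} / sum_j c_{j,tk}             relative share
    P_{i,tk}   = r_{i,tk} * P*_{tk}                    absolute population
    rho_{i,tk} = (P_{i,tk} / P_{i,tk-1}) ^ (1/dt)      hourly growth rate
    phi_{i,tk} = rho_{i,tk} / rho*_{tk}                advantage vs pool
    phi'_{i,tk}= phi_{i,tk}(sel) / phi_{i,tk}(perm)    temperature-normalized
    s_i        = prod_k phi'_{i,tk}                    cumulative advantage
    s'_i       = (s_i - s_null) / (s_wt - s_null)      control-calibrated

Across replicates, s' is averaged; its empirical standard deviation is
shrunk toward a regression-based prior using the Baldi & Long (2001)
formula before forming standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqcore import CodonVariant, AaVariant, classify_codon_variant

__all__ = [
    "CloneRecord",
    "BarcodeLibrary",
    "BarSeqCounts",
    "count_barcodes",
    "BarSeqModel",
    "BarSeqResults",
    "barseq_fitness",
    "regularize_sd",
    "fit_sd_prior",
    "aggregate_single_mutants",
]

PERMISSIVE = "permissive"
SELECTIVE = "selective"
TEMPERATURES = (PERMISSIVE, SELECTIVE)


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    genotype: tuple[CodonVariant, ...]
    control_class: str = "variant"  # variant | null_control | wt_control

    def __post_init__(self) -> None:
        if self.control_class not in ("variant", "null_control", "wt_control"):
            raise ValueError(f"bad control_class {self.control_class!r}")
        if self.control_class != "variant" and self.genotype:
            raise ValueError("control clones must have an empty genotype")

    def aa_changes(self) -> list[AaVariant]:
        """Amino-acid changes in this clone, synonymous changes dropped."""
        return [
            v.aa_variant()
            for v in self.genotype
            if classify_codon_variant(v) != "synonymous"
        ]


class BarcodeLibrary:
    """Barcode -> clone lookup for a barcoded plasmid pool."""

    def __init__(self, entries: Mapping[str, CloneRecord]):
        if len({r.clone_id for r in entries.values()}) != len(entries):
            raise ValueError("clone_ids must be unique")
        self._by_barcode = dict(entries)
        self._by_clone = {r.clone_id: r for r in entries.values()}

    def __len__(self) -> int:
        return len(self._by_barcode)

    @property
    def barcodes(self) -> list[str]:
        return list(self._by_barcode)

    @property
    def clones(self) -> list[CloneRecord]:
        return list(self._by_barcode.values())

    def clone_for_barcode(self, barcode: str) -> CloneRecord:
        return self._by_barcode[barcode]

    def clone(self, clone_id: str) -> CloneRecord:
        return self._by_clone[clone_id]

    def control_ids(self, control_class: str) -> list[str]:
        return [
            r.clone_id for r in self.clones if r.control_class == control_class
        ]

    # -- serialization ------------------------------------------------

    @staticmethod
    def _genotype_str(record: CloneRecord) -> str:
        return ";".join(str(v) for v in record.genotype)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "clone_id": [r.clone_id for r in self.clones],
                "genotype": [self._genotype_str(r) for r in self.clones],
                "control_class": [r.control_class for r in self.clones],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BarcodeLibrary":
        entries = {}
        for row in df.itertuples(index=False):
            genotype = tuple(
                CodonVariant.from_string(s)
                for s in str(row.genotype).split(";")
                if s and s != "nan"
            )
            entries[row.barcode] = CloneRecord(
                str(row.clone_id), genotype, row.control_class
            )
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


@dataclass
class BarSeqCounts:
    """Barcode counts per (timepoint, temperature, replicate) sample.

    ``counts`` is indexed by clone_id with MultiIndex columns
    (timepoint_h, temperature, replicate); ``pool_size`` maps the same
    sample triples to estimated pool cell counts (from OD readings).
    """

    counts: pd.DataFrame
    pool_size: pd.Series

    def __post_init__(self) -> None:
        tps = self.timepoints
        if len(tps) < 2 or tps[0] != 0 or any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing from 0")
        if (self.pool_size <= 0).any():
            raise ValueError("pool sizes must be positive")
        if not np.isfinite(self.counts.to_numpy()).all():
            raise ValueError("counts must be finite")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(map(tuple, self.counts.columns)) - set(
            map(tuple, self.pool_size.index)
        )
        if missing:
            raise ValueError(f"pool_size missing samples {sorted(missing)[:3]}...")

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.counts.columns.get_level_values(0).unique())

    @property
    def replicates(self) -> list:
        return sorted(self.counts.columns.get_level_values(2).unique())


# ---------------------------------------------------------------------------
# barcode counting
# ---------------------------------------------------------------------------

def _one_mismatch_index(barcodes: Sequence[str]) -> dict[str, str | None]:
    """Map each 1-mismatch neighbor to its unique barcode (None if shared)."""
    index: dict[str, str | None] = {}
    for bc in barcodes:
        for i in range(len(bc)):
            for nt in "ACGT":
                if nt == bc[i]:
                    continue
                neighbor = bc[:i] + nt + bc[i + 1 :]
                index[neighbor] = None if neighbor in index else bc
    return index


def count_barcodes(
    reads: str | Path | Iterable[str],
    library: BarcodeLibrary,
    sample_tags: Mapping[str, tuple[float, str, int]],
    pool_sizes: Mapping[tuple[float, str, int], float],
) -> tuple[BarSeqCounts, int]:
    """Count (sample tag, barcode) combinations in BarSeq reads.

    Each read is expected to begin with a sample tag immediately followed
    by the 25-nt plasmid barcode.  Barcodes match exactly or, failing
    that, to a unique library barcode at Hamming distance 1; reads whose
    barcode is ambiguous or unknown are tallied as unmatched.

    Returns the counts container and the number of unmatched reads.
    """
    tag_lens = {len(t) for t in sample_tags}
    if len(tag_lens) != 1:
        raise ValueError("sample tags must share one length")
    if len(set(sample_tags)) != len(sample_tags):
        raise ValueError("duplicate sample tags")
    tag_len = tag_lens.pop()
    bc_len = len(library.barcodes[0])

    if isinstance(reads, (str, Path)):
        seqs: Iterable[str] = (
            str(rec.seq) for rec in SeqIO.parse(str(reads), "fastq")
        )
    else:
        seqs = reads

    samples = list(sample_tags.values())
    clone_ids = [r.clone_id for r in library.clones]
    clone_pos = {cid: i for i, cid in enumerate(clone_ids)}
    sample_pos = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(clone_ids), len(samples)), dtype=np.int64)
    exact = {bc: library.clone_for_barcode(bc).clone_id for bc in library.barcodes}
    rescue = _one_mismatch_index(library.barcodes)
    unmatched = 0

    for seq in seqs:
        tag = seq[:tag_len]
        bc = seq[tag_len : tag_len + bc_len]
        sample = sample_tags.get(tag)
        if sample is None or len(bc) < bc_len:
            unmatched += 1
            continue
        cid = exact.get(bc)
        if cid is None:
            hit = rescue.get(bc)
            # a neighbor of one barcode that is within distance 1 of
            # another library barcode too is ambiguous -> unmatched
            cid = exact.get(hit) if hit is not None else None
        if cid is None:
            unmatched += 1
            continue
        mat[clone_pos[cid], sample_pos[sample]] += 1

    columns = pd.MultiIndex.from_tuples(
        samples, names=["timepoint_h", "temperature", "replicate"]
    )
    counts = pd.DataFrame(mat, index=pd.Index(clone_ids, name="clone_id"),
                          columns=columns)
    psize = pd.Series(
        {tuple(s): float(pool_sizes[tuple(s)]) for s in samples}
    ).sort_index()
    psize.index = pd.MultiIndex.from_tuples(
        psize.index, names=["timepoint_h", "temperature", "replicate"]
    )
    return BarSeqCounts(counts, psize), unmatched


# ---------------------------------------------------------------------------
# standard-deviation regularization
# ---------------------------------------------------------------------------

def regularize_sd(
    sd_emp: float | np.ndarray,
    n: int,
    prior_sd: float | np.ndarray,
    v0: float = 3.0,
) -> float | np.ndarray:
    """Bayesian shrinkage of an empirical standard deviation.

    sigma^2 = (v0 * sigma0^2 + (n - 1) * s^2) / (v0 + n - 2)

    where sigma0 is the prior estimate with v0 pseudo-degrees of freedom
    and s the empirical standard deviation over n replicates.
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    denom = v0 + n - 2
    if denom <= 0:
        raise ValueError("degenerate denominator v0 + n - 2 <= 0")
    if np.any(np.asarray(prior_sd) <= 0):
        raise ValueError("prior_sd must be positive")
    var = (v0 * np.asarray(prior_sd) ** 2 + (n - 1) * np.asarray(sd_emp) ** 2) / denom
    out = np.sqrt(var)
    return float(out) if np.isscalar(sd_emp) or np.ndim(sd_emp) == 0 else out


def fit_sd_prior(
    sd_emp: np.ndarray,
    mean_permissive_count: np.ndarray,
    s_prime: np.ndarray,
    floor: float = 1e-3,
) -> np.ndarray:
    """Regression-based prior estimate of per-clone standard deviations.

    Least-squares fit of the empirical sd on log10 mean permissive-
    condition barcode count and the fitness score; predictions are
    clamped at a positive floor.
    """
    sd_emp = np.asarray(sd_emp, dtype=float)
    ok = np.isfinite(sd_emp)
    if ok.sum() < 10:
        raise ValueError("need >= 10 clones with finite empirical sd")
    x1 = np.log10(np.maximum(np.asarray(mean_permissive_count, dtype=float), 1.0))
    x2 = np.asarray(s_prime, dtype=float)
    X = np.column_stack([np.ones_like(x1), x1, x2])
    span = X[ok].max(axis=0) - X[ok].min(axis=0)
    if np.all(span[1:] == 0):
        raise ValueError("all predictors identical; cannot fit prior")
    beta, *_ = np.linalg.lstsq(X[ok], sd_emp[ok], rcond=None)
    pred = X @ beta
    return np.maximum(pred, floor)


# ---------------------------------------------------------------------------
# fitness model
# ---------------------------------------------------------------------------

class BarSeqModel:
    """Cumulative growth-rate fitness model for a BarSeq time series.

    Parameters
    ----------
    counts
        barcode counts and pool sizes per sample.
    library
        barcode -> clone mapping including null/wt control annotations.
    pseudocount
        added to every barcode count before forming relative shares, so
        the growth-rate chain is defined at zero counts.
    v0
        pseudo-degrees of freedom given to the regression prior when
        regularizing replicate standard deviations.
    prior_floor
        lower clamp for the regression prior sd.
    """

    def __init__(
        self,
        counts: BarSeqCounts,
        library: BarcodeLibrary,
        pseudocount: float = 0.5,
        v0: float = 3.0,
        prior_floor: float = 1e-3,
    ):
        missing = set(counts.counts.index) - {r.clone_id for r in library.clones}
        if missing:
            raise ValueError(f"counts contain unknown clones {sorted(missing)[:3]}")
        for cls in ("null_control", "wt_control"):
            if not library.control_ids(cls):
                raise ValueError(f"library has no {cls} clones")
        self.counts = counts
        self.library = library
        self.pseudocount = pseudocount
        self.v0 = v0
        self.prior_floor = prior_floor

    # -- equation chain ------------------------------------------------

    def _per_replicate_scores(self) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
        c = self.counts.counts.astype(float) + self.pseudocount
        r = c / c.sum(axis=0)
        p_star = self.counts.pool_size
        P = r * p_star.reindex(r.columns).to_numpy()

        tps = self.counts.timepoints
        reps = self.counts.replicates
        intermediates: dict[str, pd.DataFrame] = {"r": r, "P": P}
        rho_cols, phi_cols = {}, {}
        for tau, rep in itertools.product(TEMPERATURES, reps):
            for k in range(1, len(tps)):
                t0, t1 = tps[k - 1], tps[k]
                dt = t1 - t0
                key = (t1, tau, rep)
                prev = (t0, tau, rep)
                if key not in P.columns or prev not in P.columns:
                    raise ValueError(f"missing sample {key} or {prev}")
                rho = (P[key] / P[prev]) ** (1.0 / dt)
                rho_star = (p_star[key] / p_star[prev]) ** (1.0 / dt)
                rho_cols[key] = rho
                phi_cols[key] = rho / rho_star
        rho_df = pd.DataFrame(rho_cols)
        phi_df = pd.DataFrame(phi_cols)
        intermediates["rho"] = rho_df
        intermediates["phi"] = phi_df

        # temperature normalization and cumulative product per replicate
        s = {}
        phi_prime_cols = {}
        for rep in reps:
            prod = pd.Series(1.0, index=phi_df.index)
            for k in range(1, len(tps)):
                t1 = tps[k]
                phi_prime = phi_df[(t1, SELECTIVE, rep)] / phi_df[(t1, PERMISSIVE, rep)]
                phi_prime_cols[(t1, rep)] = phi_prime
                prod = prod * phi_prime
            s[rep] = prod
        s_df = pd.DataFrame(s)
        intermediates["phi_prime"] = pd.DataFrame(phi_prime_cols)
        intermediates["s"] = s_df

        # calibrate against control medians, per replicate
        null_ids = self.library.control_ids("null_control")
        wt_ids = self.library.control_ids("wt_control")
        s_prime = {}
        for rep in reps:
            s_null = s_df.loc[s_df.index.intersection(null_ids), rep].median()
            s_wt = s_df.loc[s_df.index.intersection(wt_ids), rep].median()
            if s_wt == s_null:
                raise ValueError("wt and null control medians coincide")
            s_prime[rep] = (s_df[rep] - s_null) / (s_wt - s_null)
        sp_df = pd.DataFrame(s_prime)
        intermediates["s_prime"] = sp_df
        return sp_df, intermediates

    def fit(self) -> "BarSeqResults":
        sp, intermediates = self._per_replicate_scores()
        n = sp.shape[1]
        mean = sp.mean(axis=1)
        sd_emp = sp.std(axis=1, ddof=1)

        # re-anchor the replicate-averaged score so the control medians
        # are exactly 0 and 1 (averaging per-replicate-anchored scores
        # preserves them only approximately)
        null_med = mean.loc[
            mean.index.intersection(self.library.control_ids("null_control"))
        ].median()
        wt_med = mean.loc[
            mean.index.intersection(self.library.control_ids("wt_control"))
        ].median()
        span = wt_med - null_med
        if span == 0:
            raise ValueError("wt and null control medians coincide")
        mean = (mean - null_med) / span
        sd_emp = sd_emp / abs(span)

        perm_cols = [c for c in self.counts.counts.columns if c[1] == PERMISSIVE]
        mean_perm = self.counts.counts[perm_cols].mean(axis=1)
        if n >= 2 and np.isfinite(sd_emp.to_numpy()).sum() >= 10:
            prior = fit_sd_prior(
                sd_emp.to_numpy(), mean_perm.to_numpy(), mean.to_numpy(),
                floor=self.prior_floor,
            )
            sd_reg = regularize_sd(sd_emp.to_numpy(), n, prior, self.v0)
        else:
            # micro-instances: too few clones/replicates for the
            # regression prior; report the empirical sd unshrunk
            prior = np.full(len(sd_emp), np.nan)
            sd_reg = sd_emp.to_numpy()
        se = sd_reg / np.sqrt(n)

        records = pd.DataFrame(
            {
                "clone_id": sp.index,
                "s_prime": mean.to_numpy(),
                "sd_emp": sd_emp.to_numpy(),
                "sd_prior": prior,
                "sd_reg": sd_reg,
                "se": se,
                "df": n,
            }
        ).set_index("clone_id")
        records["control_class"] = [
            self.library.clone(cid).control_class for cid in records.index
        ]
        return BarSeqResults(self, records, intermediates)


def barseq_fitness(
    counts: BarSeqCounts,
    library: BarcodeLibrary,
    pseudocount: float = 0.5,
    v0: float = 3.0,
) -> "BarSeqResults":
    """Functional wrapper around :class:`BarSeqModel`."""
    return BarSeqModel(counts, library, pseudocount=pseudocount, v0=v0).fit()


class BarSeqResults:
    """Per-clone fitness records plus growth intermediates."""

    def __init__(
        self,
        model: BarSeqModel,
        clone_scores: pd.DataFrame,
        intermediates: dict[str, pd.DataFrame],
    ):
        self.model = model
        self.clone_scores = clone_scores
        self.intermediates = intermediates

    @property
    def s_prime_replicates(self) -> pd.DataFrame:
        return self.intermediates["s_prime"]

    def variant_scores(self, gene: str = "GENE") -> pd.DataFrame:
        """Single-mutant clone scores aggregated per amino-acid variant."""
        return aggregate_single_mutants(self.clone_scores, self.model.library, gene)

    def summary(self) -> str:
        cs = self.clone_scores
        null_med = cs.loc[cs.control_class == "null_control", "s_prime"].median()
        wt_med = cs.loc[cs.control_class == "wt_control", "s_prime"].median()
        lines = [
            "BarSeq fitness results",
            "=" * 38,
            f"clones scored        {len(cs):>10d}",
            f"replicates           {int(cs['df'].iloc[0]):>10d}",
            f"null-control median  {null_med:>10.4f}",
            f"wt-control median    {wt_med:>10.4f}",
            f"median regularized se{cs['se'].median():>10.4f}",
        ]
        return "\n".join(lines)


def aggregate_single_mutants(
    clone_scores: pd.DataFrame,
    library: BarcodeLibrary,
    gene: str = "GENE",
) -> pd.DataFrame:
    """Inverse-variance weighted variant scores from single-mutant clones.

    Clones carrying exactly one amino-acid change (synonymous codon
    changes ignored) are biological replicates of that variant; their
    calibrated scores are combined with weights 1 / se^2.
    """
    groups: dict[AaVariant, list[str]] = {}
    for record in library.clones:
        if record.control_class != "variant":
            continue
        changes = record.aa_changes()
        if len(changes) == 1 and record.clone_id in clone_scores.index:
            groups.setdefault(changes[0], []).append(record.clone_id)

    rows = []
    for variant, clone_ids in sorted(
        groups.items(), key=lambda kv: (kv[0].position, kv[0].mut_aa)
    ):
        sub = clone_scores.loc[clone_ids]
        w = 1.0 / sub["se"] ** 2
        score = float((w * sub["s_prime"]).sum() / w.sum())
        se = float(np.sqrt(1.0 / w.sum()))
        sd = float(np.sqrt((w * sub["sd_reg"] ** 2).sum() / w.sum()))
        rows.append(
            {
                "gene": gene,
                "position": variant.position,
                "wt_aa": variant.wt_aa,
                "mut_aa": variant.mut_aa,
                "score": score,
                "sd": sd,
                "se": se,
                "df": int(sub["df"].sum()),
                "provenance": "measured",
                "n_clones": len(clone_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "position", "wt_aa", "mut_aa", "score", "sd", "se", "df",
            "provenance", "n_clones",
        ],
    )
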