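"""POPCode mutagenic oligo design.

POPCode saturation mutagenesis replaces every codon of an ORF with an NNK
degenerate codon (N = any base, K = G/T) carried on a mutagenic oligo.
The flanking arms of each oligo are extended until their predicted melting
temperature reaches a common target, so that hybridisation — and hence the
mutation rate — is as uniform as possible along the ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .seqcore import GeneticCode, OrfSequence, STANDARD_CODE, NUCLEOTIDES

__all__ = [
    "DesignConfig",
    "MutagenicOligo",
    "nnk_table",
    "predict_tm",
    "design_popcode_oligos",
    "write_oligo_table",
]

NNK_THIRD_BASES = "GT"


@dataclass(frozen=True)
class DesignConfig:
    """Parameters for oligo design.

    tm_target
        arm melting-temperature target in degrees Celsius.
    arm_min, arm_max
        allowed arm lengths in nucleotides.
    salt_mM
        monovalent cation concentration for the nearest-neighbor model.
    oligo_nM
        oligo concentration for the nearest-neighbor model.
    """

    tm_target: float = 60.0
    arm_min: int = 10
    arm_max: int = 40
    salt_mM: float = 50.0
    oligo_nM: float = 50.0

    def __post_init__(self) -> None:
        if self.arm_min < 10:
            raise ValueError("arm_min must be >= 10")
        if not 40.0 <= self.tm_target <= 75.0:
            raise ValueError("tm_target must be within 40-75 degC")
        if self.arm_min > self.arm_max:
            raise ValueError("arm_min > arm_max")


@dataclass(frozen=True)
class MutagenicOligo:
    codon_index: int
    left_arm: str
    right_arm: str
    tm_left: float
    tm_right: float

    @property
    def sequence(self) -> str:
        return self.left_arm + "NNK" + self.right_arm


def nnk_table(code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """The 32 NNK codons and the amino acids they encode.

    NNK (K = G or T) covers all 20 amino acids while admitting only one
    stop codon (TAG; TAA and TGA end in A).
    """
    rows = [
        {"codon": a + b + k, "aa": code[a + b + k]}
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for k in NNK_THIRD_BASES
    ]
    return pd.DataFrame(rows)


def nnk_summary(code: GeneticCode = STANDARD_CODE) -> dict:
    """Composition statistics of the NNK codon set."""
    table = nnk_table(code)
    aas = table["aa"]
    return {
        "n_codons": len(table),
        "n_distinct_aa": aas[aas != "*"].nunique(),
        "stop_codons": sorted(table.loc[aas == "*", "codon"]),
    }


def predict_tm(seq: str, cfg: DesignConfig = DesignConfig()) -> float:
    """Nearest-neighbor melting temperature (degC) of a DNA sequence.

    Uses the SantaLucia (2004) unified parameter set with the configured
    monovalent salt and oligo concentrations.  Degenerate bases are not
    allowed: arms are exact wild-type sequence.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short for a meaningful Tm")
    if set(seq) - set(NUCLEOTIDES):
        raise ValueError(f"degenerate or invalid bases in {seq!r}")
    return float(
        MeltingTemp.Tm_NN(
            seq,
            nn_table=MeltingTemp.DNA_NN4,
            Na=cfg.salt_mM,
            dnac1=cfg.oligo_nM,
            dnac2=cfg.oligo_nM,
        )
    )


def _grow_arm(flank: str, cfg: DesignConfig, from_right: bool) -> tuple[str, float]:
    """Shortest arm with Tm >= target, grown outward one nt at a time.

    ``flank`` is the full available flanking sequence, oriented so that
    the arm grows from its target-codon-proximal end.  ``from_right``
    selects whether the arm is the suffix (left arm) or prefix (right
    arm) of the flank.
    """
    max_len = min(cfg.arm_max, len(flank))
    for n in range(cfg.arm_min, max_len + 1):
        arm = flank[-n:] if from_right else flank[:n]
        tm = predict_tm(arm, cfg)
        if tm >= cfg.tm_target:
            return arm, tm
    arm = flank[-max_len:] if from_right else flank[:max_len]
    tm = predict_tm(arm, cfg)
    warnings.warn(
        f"tm_target {cfg.tm_target} unreachable within arm_max={cfg.arm_max}; "
        f"using maximal arm (Tm {tm:.1f})"
    )
    return arm, tm


def design_popcode_oligos(
    orf: OrfSequence,
    cfg: DesignConfig = DesignConfig(),
    codons_targeted: range | None = None,
    on_insufficient_flank: str = "error",
) -> list[MutagenicOligo]:
    """One NNK replacement oligo per targeted codon.

    By default all codons except the initiator ATG and the stop codon are
    targeted.  Each arm is the shortest extension of the wild-type flank
    whose predicted Tm reaches ``cfg.tm_target``, capped at ``arm_max``;
    design is fully deterministic.  Codons too close to the ORF ends for
    ``arm_min`` raise an error, or are skipped with
    ``on_insufficient_flank="skip"`` (edge codons are normally covered
    by extending the amplicon into vector sequence).
    """
    if on_insufficient_flank not in ("error", "skip"):
        raise ValueError("on_insufficient_flank must be 'error' or 'skip'")
    if codons_targeted is None:
        codons_targeted = range(2, orf.n_codons)  # skip Met1 and stop
    nt = orf.nucleotides
    oligos = []
    for idx in codons_targeted:
        if not 1 <= idx <= orf.n_codons:
            raise ValueError(f"codon {idx} outside ORF")
        start = (idx - 1) * 3
        left_flank = nt[:start]
        right_flank = nt[start + 3 :]
        if len(left_flank) < cfg.arm_min or len(right_flank) < cfg.arm_min:
            if on_insufficient_flank == "skip":
                continue
            raise ValueError(
                f"codon {idx}: insufficient flank for arm_min={cfg.arm_min}"
            )
        left_arm, tm_left = _grow_arm(left_flank, cfg, from_right=True)
        right_arm, tm_right = _grow_arm(right_flank, cfg, from_right=False)
        oligos.append(MutagenicOligo(idx, left_arm, right_arm, tm_left, tm_right))
    return oligos


def write_oligo_table(oligos: list[MutagenicOligo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "codon_index": [o.codon_index for o in oligos],
            "sequence": [o.sequence for o in oligos],
            "left_arm_len": [len(o.left_arm) for o in oligos],
            "right_arm_len": [len(o.right_arm) for o in oligos],
            "tm_left": [round(o.tm_left, 2) for o in oligos],
            "tm_right": [round(o.tm_right, 2) for o in oligos],
        }
    ).to_csv(path, sep="\t", index=False)
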