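"""Nearest-neighbor duplex thermodynamics for 19-bp siRNA duplexes.

The stability features are the 18 internal base-pair stacks of the duplex,
indexed along the antisense (guide) strand: stack k spans antisense
positions k and k+1 (k = 1..18, 5'->3').  ``whole_dG`` is the plain sum of
those 18 stacking free energies at 37 C, in kcal/mol, with no duplex
initiation or terminal corrections; dH (kcal/mol) and dS (cal/(mol K)) are
summed the same way.  The default parameter table is the RNA Watson-Crick
nearest-neighbor set of Xia et al. (1998), shipped as editable TSV package
data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import ValidationError, normalize_sequence, reverse_complement

_ALL_STEPS = tuple(a + b for a in "ACGU" for b in "ACGU")
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor parameter table for the 16 Watson-Crick steps.

    Keys are the top-strand dinucleotide read 5'->3' (the paired strand is
    implied by complementarity).  Units: ``stack_dG37`` and ``stack_dH`` in
    kcal/mol, ``stack_dS`` in cal/(mol K).
    """

    stack_dG37: dict[str, float]
    stack_dH: dict[str, float]
    stack_dS: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (
            ("dG37", self.stack_dG37),
            ("dH", self.stack_dH),
            ("dS", self.stack_dS),
        ):
            missing = [s for s in _ALL_STEPS if s not in table]
            if missing:
                raise ValidationError(
                    f"thermo parameter table {name} missing steps {missing}"
                )


@dataclass(frozen=True)
class ThermoFeatures:
    """Thermodynamic feature values for one 19-nt siRNA.

    ``stacks`` holds the 18 antisense-step stacking dG37 values 5'->3'
    (kcal/mol); ``whole_dG`` is their sum; ``dH``/``dS`` are whole-duplex
    sums of the enthalpy and entropy parameters.
    """

    stacks: tuple[float, ...]
    whole_dG: float
    dH: float
    dS: float


def _parse_step(raw: str) -> str:
    """Validate a 'XY/X'Y'' step label and return the top-strand key XY."""
    top, _, bottom = raw.partition("/")
    top = normalize_sequence(top)
    if len(top) != 2:
        raise ValidationError(f"step label {raw!r}: top strand must be 2 nt")
    if bottom:
        expect = "".join(_COMP[b] for b in top)
        if normalize_sequence(bottom) != expect:
            raise ValidationError(
                f"step label {raw!r}: bottom strand is not the aligned "
                f"complement of {top} (expected {expect})"
            )
    return top


def load_thermo_params(path: str | os.PathLike | None = None) -> ThermoParams:
    """Load a nearest-neighbor table from TSV (default: shipped Xia 1998 set).

    Expected columns: ``step`` ("XY/X'Y'" top 5'->3' / bottom 3'->5'),
    ``dG37``, ``dH``, ``dS``.  Lines starting with '#' are comments.
    """
    if path is None:
        src = resources.files("sirnakit.data").joinpath("nn_stacks_rna_wc.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    need = {"step", "dG37", "dH", "dS"}
    if not need <= set(df.columns):
        raise ValidationError(
            f"thermo table needs columns {sorted(need)}, got {list(df.columns)}"
        )
    dG, dH, dS = {}, {}, {}
    for row in df.itertuples(index=False):
        key = _parse_step(str(row.step))
        dG[key] = float(row.dG37)
        dH[key] = float(row.dH)
        dS[key] = float(row.dS)
    return ThermoParams(dG, dH, dS)


def compute_thermo(seq: str, params: ThermoParams | None = None) -> ThermoFeatures:
    """Compute stacking features for a 19-nt sense-strand sequence.

    The antisense strand is derived as the reverse complement; stack k is
    the nearest-neighbor dG37 of the antisense dinucleotide at positions
    (k, k+1).
    """
    if params is None:
        params = default_params()
    seq = normalize_sequence(seq)
    if len(seq) != 19:
        raise ValidationError(f"thermo features need a 19-nt sequence, got {len(seq)}")
    antisense = reverse_complement(seq)
    stacks, dHs, dSs = [], [], []
    for k in range(18):
        step = antisense[k : k + 2]
        try:
            stacks.append(params.stack_dG37[step])
            dHs.append(params.stack_dH[step])
            dSs.append(params.stack_dS[step])
        except KeyError:
            raise ValidationError(f"no thermodynamic parameters for step {step!r}")
    return ThermoFeatures(
        stacks=tuple(stacks),
        whole_dG=float(np.sum(stacks)),
        dH=float(np.sum(dHs)),
        dS=float(np.sum(dSs)),
    )


def whole_dG(seq: str, params: ThermoParams | None = None) -> float:
    """Whole-duplex stacking free energy (kcal/mol) of a 19-nt siRNA."""
    return compute_thermo(seq, params).whole_dG


_DEFAULT: ThermoParams | None = None


def default_params() -> ThermoParams:
    """The shipped Xia et al. (1998) RNA parameter set, cached."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_thermo_params()
    return _DEFAULT
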