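"""Synthetic siRNA datasets with planted, recoverable structure.

Real siRNA screens (thousands of 19-mers with measured percent knockdown)
are external publications' supplements; this generator emulates their
shape so the whole pipeline is testable offline.  Sequences are drawn
uniformly over {A,C,G,U}^19 and efficacy is

    clip(50 + effect_size * z(signal) + Normal(0, noise_sd), 0, 100)

where z(.) standardizes the planted signal over the sample.  Three signal
models are available:

* ``gc_linear``    — signal is the GC count of the 19-mer;
* ``thermo_linear`` — signal is -whole_dG, i.e. duplex stacking
  stability (efficacy then correlates negatively with whole_dG, the
  direction seen in real screens);
* ``motif_rules``  — signal is a weighted sum of position-specific
  nucleotide indicators (a design-rule-like signal).

Identical (spec, seed) pairs reproduce identical datasets bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, SiRNARecord, ValidationError
from .thermo import ThermoParams, whole_dG

SIGNAL_MODELS = ("gc_linear", "thermo_linear", "motif_rules")

#: (position, nucleotide, weight) triples planted by the motif_rules model.
DEFAULT_MOTIFS: tuple[tuple[int, str, float], ...] = (
    (19, "A", 1.0),
    (10, "U", 1.0),
    (1, "G", 1.0),
    (13, "G", -1.0),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    ``noise_sd`` is the s.d. of the additive Gaussian noise on the percent
    scale; ``effect_size`` is the efficacy swing (percentage points) per
    standard deviation of the planted signal.
    """

    n_records: int = 500
    seed: int = 0
    signal_model: str = "gc_linear"
    noise_sd: float = 10.0
    effect_size: float = 20.0
    motifs: tuple[tuple[int, str, float], ...] = DEFAULT_MOTIFS
    thermo_params: ThermoParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValidationError("n_records must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.signal_model not in SIGNAL_MODELS:
            raise ValidationError(
                f"unknown signal_model {self.signal_model!r}; "
                f"choose from {SIGNAL_MODELS}"
            )


def _signal(seqs: list[str], spec: SyntheticSpec) -> np.ndarray:
    if spec.signal_model == "gc_linear":
        return np.array([s.count("G") + s.count("C") for s in seqs], dtype=float)
    if spec.signal_model == "thermo_linear":
        return np.array([-whole_dG(s, spec.thermo_params) for s in seqs])
    sig = np.zeros(len(seqs))
    for pos, nuc, w in spec.motifs:
        sig += w * np.array([1.0 if s[pos - 1] == nuc else 0.0 for s in seqs])
    return sig


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw one dataset according to ``spec`` (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list("ACGU"))
    seqs = [
        "".join(letters[rng.integers(0, 4, size=19)]) for _ in range(spec.n_records)
    ]
    sig = _signal(seqs, spec)
    sd = sig.std()
    z = (sig - sig.mean()) / sd if sd > 0 else np.zeros_like(sig)
    eff = 50.0 + spec.effect_size * z + rng.normal(0.0, spec.noise_sd, spec.n_records)
    eff = np.clip(eff, 0.0, 100.0)
    records = [
        SiRNARecord(f"syn{i + 1}", s, float(e))
        for i, (s, e) in enumerate(zip(seqs, eff))
    ]
    return Dataset(records, name=f"synthetic_{spec.signal_model}_{spec.seed}")
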