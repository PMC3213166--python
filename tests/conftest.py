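import numpy as np
import pytest

from sirnakit import Dataset, RuleTable, SiRNARecord, dataset_from_arrays


def random_sequences(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACGU"))
    return ["".join(letters[rng.integers(0, 4, 19)]) for _ in range(n)]


@pytest.fixture
def toy_rules() -> RuleTable:
    """A 12-set rule table with known verdicts at a few positions."""
    sets = tuple(f"set{i}" for i in range(1, 13))
    verdict = {
        ("set1", 3, "A"): 1,  # mimics 'A at position 3 favored'
        ("set2", 3, "A"): -1,  # a conflicting set: allowed across sets
        ("set3", 19, "U"): 1,
        ("set4", 1, "G"): -1,
    }
    return RuleTable(sets, verdict)


@pytest.fixture
def balanced_pos1_dataset() -> Dataset:
    """Efficacy is 100 iff position 1 is A, on a balanced design."""
    base = "CGUACGUACGUACGUACG"  # 18 nt tail
    records = []
    for i in range(10):
        records.append(SiRNARecord(f"a{i}", "A" + base, 100.0))
        records.append(SiRNARecord(f"g{i}", "G" + base, 0.0))
    return Dataset(records, name="balanced")


@pytest.fixture
def small_random_dataset() -> Dataset:
    rng = np.random.default_rng(42)
    seqs = random_sequences(50, 42)
    eff = rng.uniform(0, 100, 50)
    return dataset_from_arrays(seqs, eff, name="random50")
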