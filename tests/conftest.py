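import pytest

from msapkit.core import BandTypeCounts


@pytest.fixture
def ck_counts() -> BandTypeCounts:
    """Control-group band-type counts."""
    return BandTypeCounts(704, 40, 33, 26)


@pytest.fixture
def az_counts() -> BandTypeCounts:
    """Treated-group band-type counts."""
    return BandTypeCounts(700, 32, 35, 18)


@pytest.fixture
def class_counts_14() -> dict[str, int]:
    """The 14 transition-class counts (409 classified loci)."""
    return {
        "A1": 312, "A2": 24, "A3": 21,
        "B1": 15, "B2": 4, "B3": 5, "B4": 9, "B5": 4,
        "C1": 4, "C2": 6, "C3": 0, "C4": 0, "C5": 4, "C6": 1,
    }
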