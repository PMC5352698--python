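import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_config():
    """A small two-class enumeration: 12 Cer[NS] + 4 SM structures."""
    from sphingolib.nomenclature import EnumerationConfig

    return EnumerationConfig.from_dict(
        {
            "classes": {
                "Cer[NS]": {
                    "fa_carbons": [16, 18],
                    "fa_double_bonds": [0, 0],
                    "base_carbons": [18, 18],
                    "base_double_bonds": [1, 2],
                    "parity": "even",
                    "adducts": ["[M-H]-", "[M+HCOO]-", "[M+CH3COO]-"],
                },
                "SM": {
                    "fa_carbons": [16, 17],
                    "fa_double_bonds": [0, 0],
                    "base_carbons": [18, 18],
                    "base_double_bonds": [1, 2],
                    "adducts": ["[M+HCOO]-", "[M+CH3COO]-"],
                },
            }
        }
    )


@pytest.fixture(scope="session")
def toy_library(toy_config):
    from sphingolib.fragmentation import build_library

    return build_library(toy_config)


@pytest.fixture(scope="session")
def recovery_library():
    """Two ceramide classes over moderate ranges (630 records, one adduct),
    used for seeded rank-1 recovery simulations."""
    from sphingolib.fragmentation import build_library
    from sphingolib.nomenclature import EnumerationConfig

    ranges = {
        "fa_carbons": [14, 20],
        "fa_double_bonds": [0, 2],
        "base_carbons": [16, 20],
        "base_double_bonds": [0, 2],
        "adducts": ["[M+CH3COO]-"],
    }
    config = EnumerationConfig.from_dict(
        {"classes": {"Cer[NS]": dict(ranges), "Cer[AS]": dict(ranges)}}
    )
    return build_library(config)
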