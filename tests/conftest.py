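import numpy as np
import pandas as pd
import pytest

import hlakit as hk


@pytest.fixture
def tiny_calls() -> hk.HlaCalls:
    """Six individuals, genes A and DQB1, with one missing call."""
    frame = pd.DataFrame(
        {
            "A_1": ["A*02:01", "A*02:01", "A*01:01", "A*02:01", "A*03:01", None],
            "A_2": ["A*02:01", "A*01:01", "A*01:01", "A*03:01", "A*03:01", "A*01:01"],
            "DQB1_1": ["DQB1*03:01", "DQB1*02:01", "DQB1*03:01",
                       "DQB1*05:01", "DQB1*02:01", "DQB1*03:01"],
            "DQB1_2": ["DQB1*03:01", "DQB1*03:01", "DQB1*02:01",
                       "DQB1*05:01", "DQB1*05:01", "DQB1*02:01"],
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="ID"),
    )
    return hk.HlaCalls(frame)


@pytest.fixture
def dqb1_alignment() -> hk.AlignmentTable:
    """Handcrafted DQB1 alignment: F/Y/L at position 9, A/D at 57,
    an unknown and an indel row, 2-field rows plus one 4-field row."""
    text = "\n".join([
        "# gene=DQB1",
        "# positions=7,8,9,57,60",
        "DQB1*03:01\tGPYAE",       # reference: Y at 9, A at 57
        "DQB1*02:01\t--F-D",
        "DQB1*05:01\t--LD-",
        "DQB1*06:01\t*----",
        "DQB1*04:01\t.-F--",
        "DQB1*03:01:01:01\t-----",
    ]) + "\n"
    return hk.parse_alignment(text)


@pytest.fixture
def supertype_dict() -> hk.Dictionary:
    return hk.load_supertypes()


@pytest.fixture
def nk_dict() -> hk.Dictionary:
    return hk.load_nk_ligands()


@pytest.fixture
def grantham() -> hk.GranthamMatrix:
    return hk.load_grantham_matrix()


def random_calls(seed: int, n: int = 20) -> hk.HlaCalls:
    """Random small cohort over the default synthetic frequency tables."""
    cfg = hk.SimConfig(n_individuals=n, seed=seed)
    return hk.gen_hla_calls(cfg)
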