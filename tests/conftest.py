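import textwrap

import pytest

from opsinevol.io_formats import CodonAlignment


@pytest.fixture
def tiny_alignment() -> CodonAlignment:
    return CodonAlignment(
        taxa=("A", "B", "C"),
        sequences=("ATGAAATTT", "ATGAAGTTC", "ATGAAATTC"),
    )


# --- synthetic codeml-style output fixtures (PAML 4.x NSsites dialect) ----

CODEML_M7 = textwrap.dedent("""\
    CODONML (in paml version 4.4, March 2010)  synthetic fixture
    Model 7: beta (10 categories)

    lnL(ntime: 93  np: 96): -1234.500000     +0.000000

    dN/dS (w) for site classes (K=10)

    p:   0.10000  0.10000  0.10000  0.10000  0.10000  0.10000  0.10000  0.10000  0.10000  0.10000
    w:   0.01000  0.03000  0.06000  0.10000  0.15000  0.21000  0.28000  0.36000  0.45000  0.55000
    """)

CODEML_M8 = textwrap.dedent("""\
    CODONML (in paml version 4.4, March 2010)  synthetic fixture
    Model 8: beta&w>1 (11 categories)

    lnL(ntime: 93  np: 98): -1230.250000     +0.000000

    dN/dS (w) for site classes (K=11)

    p:   0.09000  0.09000  0.09000  0.09000  0.09000  0.09000  0.09000  0.09000  0.09000  0.09000  0.10000
    w:   0.01000  0.03000  0.06000  0.10000  0.15000  0.21000  0.28000  0.36000  0.45000  0.55000  1.50000
    """)

CODEML_TWO_RATIO = textwrap.dedent("""\
    CODONML (in paml version 4.4, March 2010)  synthetic fixture
    Model 2: 2 dN/dS ratios for branches

    lnL(ntime: 93  np: 95): -1228.000000     +0.000000

    w (dN/dS) for branches:  0.14600 0.54800
    """)

CODEML_ONE_RATIO = textwrap.dedent("""\
    CODONML (in paml version 4.4, March 2010)  synthetic fixture
    Model 0: one dN/dS ratio

    lnL(ntime: 93  np: 94): -1231.750000     +0.000000

    omega (dN/dS) =  0.20310
    """)


@pytest.fixture
def codeml_files(tmp_path):
    paths = {}
    for name, text in [("m7", CODEML_M7), ("m8", CODEML_M8),
                       ("two_ratio", CODEML_TWO_RATIO),
                       ("one_ratio", CODEML_ONE_RATIO)]:
        p = tmp_path / f"{name}.txt"
        p.write_text(text)
        paths[name] = p
    return paths
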