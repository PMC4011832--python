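import numpy as np
import pandas as pd
import pytest

from orqprofiler.core_model import (
    Assay, AssayPanel, CqMatrix, OrClass, Role, load_default_panel,
)
from orqprofiler.synthetic_tlda import GeneratorConfig


@pytest.fixture(scope="session")
def default_panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Compact panel for fast generator tests: 20 ORs + full reference set."""
    assays = [Assay("GAPDH_m", "GAPDH", Role.INTERNAL_CONTROL, intron_spanning=True)]
    for g in ("MRPL19", "CASC3", "POLR2A", "CDKN1B", "TBP", "RPL30",
              "PSMC4", "YWHAZ", "UBC", "PPIA"):
        assays.append(Assay(g + "_m", g, Role.ENDOGENOUS_REF, intron_spanning=True))
    for g in ("CNGA2", "GNAL", "ADCY3", "RIC8B", "RTP1", "OBP2A2B"):
        assays.append(Assay(g + "_m", g, Role.OE_REF, intron_spanning=True))
    for i in range(20):
        assays.append(Assay(f"OR1T{i + 1}", f"OR1T{i + 1}", Role.OR_TARGET,
                            OrClass.CLASS_II))
    return AssayPanel(assays)


@pytest.fixture
def toy_cq():
    values = pd.DataFrame(
        [[20.0, 30.0, np.nan], [21.0, 29.5, 35.0]],
        index=["s1", "s2"], columns=["A1", "A2", "A3"],
    )
    return CqMatrix(values,
                    pd.Series({"s1": "run1", "s2": "run1"}),
                    pd.Series({"s1": "rt_plus", "s2": "rt_plus"}))


@pytest.fixture
def quiet_config():
    """All noise off: Cq equals the gene baseline everywhere."""
    return GeneratorConfig(
        n_samples=4,
        endogenous_ref_params={g: (m, 0.0) for g, (m, _) in
                               GeneratorConfig().endogenous_ref_params.items()},
        oe_ref_params={g: (m, 0.0) for g, (m, _) in
                       GeneratorConfig().oe_ref_params.items()},
        or_noise_sd=0.0, or_dropout_rate=0.0,
        neuron_fraction_sd=0.0, technical_loading_sd=0.0,
    )
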