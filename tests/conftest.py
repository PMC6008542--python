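import numpy as np
import pytest

from scclfp.synth import SyntheticCohortSpec, synthesize_cohort


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 3-patient synthetic cohort on disk (EDF + sidecars).

    Patient 1 carries an edge effective contact (L4, no differential),
    patient 2 a fully artifact-annotated pre epoch, patient 3 is a
    non-responder — every pipeline error path is represented.
    """
    outdir = tmp_path_factory.mktemp("cohort")
    spec = SyntheticCohortSpec(n_patients=3, n_responders=2, master_seed=11)
    synthesize_cohort(spec, outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
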