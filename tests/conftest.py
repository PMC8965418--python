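import numpy as np
import pytest

from foidecomp import TransmissionReplicate


def make_replicate(
    replicate_id="r0",
    treatment="intraspecific",
    source="focal_sourced",
    worms_added=10,
    on_donor=0,
    on_receiver=0,
    in_donor_cup=0,
    in_experimental_cup=0,
    in_receiver_cup=0,
    duration_hours=18.0,
):
    return TransmissionReplicate(
        replicate_id=replicate_id,
        treatment=treatment,
        source=source,
        worms_added=worms_added,
        on_donor=on_donor,
        on_receiver=on_receiver,
        in_donor_cup=in_donor_cup,
        in_experimental_cup=in_experimental_cup,
        in_receiver_cup=in_receiver_cup,
        duration_hours=duration_hours,
    )


@pytest.fixture
def replicate_factory():
    return make_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(20230920)
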