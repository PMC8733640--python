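import pytest

from cornea_emod.airpuff import AirPuffConfig
from cornea_emod.shell import CorneaGeometry
from cornea_emod.synth import SimConfig, SubjectRecord, simulate_examination


@pytest.fixture(scope="session")
def healthy_geometry():
    """Group-mean healthy geometry (CCT 534.5 um, R 7.75 mm, nu 0.49)."""
    return CorneaGeometry(R=7.75, t=0.5345)


@pytest.fixture(scope="session")
def airpuff():
    return AirPuffConfig()


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, motion-free simulation settings."""
    return SimConfig(noise_sigma=0.0, eye_motion_a=0.0)


def make_subject(E=0.35, geometry=None, seed=42, group="healthy", bIOP=15.3):
    return SubjectRecord(
        subject_id=f"{group}-test",
        group=group,
        E_true=E,
        geometry=geometry or CorneaGeometry(R=7.75, t=0.5345),
        bIOP=bIOP,
        aux_features={},
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_exam(healthy_geometry, airpuff, clean_sim):
    """One noiseless healthy examination at E = 0.35 MPa."""
    return simulate_examination(make_subject(), airpuff, clean_sim)
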