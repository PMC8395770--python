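import pytest

from gxtrans.io import load_example_gxt
from gxtrans.metabolic import Workload
from gxtrans.translation import GxtRecord, Subject


@pytest.fixture
def table3_record():
    """The packaged worked-example GXT: Balke-type, rest 70 bpm to max 160."""
    return load_example_gxt()


def make_linear_record(hr_rest=70.0, hr_max=160.0, duration=600.0, n_stages=10):
    """A GXT whose stage-end HR is exactly linear in time."""
    subject = Subject(hr_rest, hr_max, id="linear")
    dt = duration / n_stages
    stages = [(0.0, Workload(0.0, 0.0))]
    hr = [(0.0, hr_rest)]
    rpe = [(0.0, 6.0)]
    for k in range(1, n_stages + 1):
        t = k * dt
        stages.append((t, Workload(80.4, 0.02 * k)))
        hr.append((t, hr_rest + (hr_max - hr_rest) * t / duration))
        rpe.append((t, 6.0 + 14.0 * t / duration))
    return GxtRecord(subject, tuple(stages), tuple(hr), tuple(rpe))


@pytest.fixture
def linear_record():
    return make_linear_record()
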