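import numpy as np
import pytest

from m2mcalib import AcquisitionMeta, RFFrame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frame(samples, machine_id="machineA", phantom_id="ph", rate=40e6,
               mode="freehand", index=0, class_label=None):
    return RFFrame(
        samples=samples,
        meta=AcquisitionMeta(
            machine_id=machine_id,
            phantom_id=phantom_id,
            sampling_rate=rate,
            acquisition_mode=mode,
            frame_index=index,
            class_label=class_label,
        ),
    )


@pytest.fixture
def frame_factory():
    return make_frame
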