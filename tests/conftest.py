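"""Shared test configuration.

BLAS/OpenMP thread pools are pinned to one thread before NumPy is imported
so that reduction orders — and therefore trained parameters and predicted
probabilities — are bitwise reproducible across machines.
"""

import os

for _var in (
    "OMP_NUM_THREADS",
    "OPENBLAS_NUM_THREADS",
    "MKL_NUM_THREADS",
    "NUMEXPR_NUM_THREADS",
):
    os.environ.setdefault(_var, "1")

from hypothesis import HealthCheck, settings  # noqa: E402

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")
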