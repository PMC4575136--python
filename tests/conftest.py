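import numpy as np
import pytest

from yauhausdorff import YauOptions, default_dna_mapping


@pytest.fixture(scope="session")
def dna_mapping():
    return default_dna_mapping()


@pytest.fixture
def alignment_only():
    """Options with no random rotations: fully deterministic geometry."""
    return YauOptions(n_random=0)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(content: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def random_point_set(rng: np.ndarray, n: int, scale: float = 5.0) -> np.ndarray:
    return rng.uniform(-scale, scale, size=(n, 2))


def decode_dna_curve(points: np.ndarray, mapping) -> str:
    """Test utility: invert a DNA curve back to its sequence via y-steps."""
    inv = {round(dy, 9): res for res, (_, dy) in mapping.steps.items()}
    out = []
    for k in range(1, len(points)):
        dy = points[k, 1] - points[k - 1, 1]
        key = min(inv, key=lambda v: abs(v - dy))
        assert abs(key - dy) < 1e-9
        out.append(inv[key])
    return "".join(out)
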