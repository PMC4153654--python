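from pathlib import Path

import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def toy_paths(data_dir: Path) -> dict[str, Path]:
    """Committed hand-specified toy dataset (50 PSMs)."""
    return {
        "psms": data_dir / "toy_psms.tsv",
        "source_fasta": data_dir / "toy_source.fasta",
        "human_fasta": data_dir / "toy_human.fasta",
        "pairs": data_dir / "toy_pairs.tsv",
        "known_sites": data_dir / "toy_known_sites.tsv",
        "expected_results": data_dir / "toy_expected_results.tsv",
    }
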