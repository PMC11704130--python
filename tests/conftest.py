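import numpy as np
import pandas as pd
import pytest

from headconc.lexicon import Lexicon

#: Ratings used across scorer tests.  "tomato"/"sound"/"idea" carry the
#: published reference values; the rest are arbitrary fixture ratings.
FIXTURE_RATINGS = {
    "tomato": 5.0,
    "sound": 3.7,
    "idea": 1.62,
    "visit": 3.92,
    "elephant": 4.5,
    "lounge": 3.5,
    "great": 2.2,
    "super": 2.0,
    "spectacular": 3.0,
    "freedom": 2.1,
    "baby": 4.9,
    "dog": 4.85,
    "story": 3.3,
    "secret": 2.5,
    "reason": 1.9,
    "love": 2.07,
    "got": 2.8,
    "about": 1.5,
    "watch": 4.0,
    "happy": 2.56,
    "big": 3.05,
    "try": 2.4,
}


@pytest.fixture(scope="session")
def tiny_lexicon() -> Lexicon:
    return Lexicon.from_mapping(FIXTURE_RATINGS)


@pytest.fixture()
def lexicon_file(tmp_path):
    path = tmp_path / "lexicon.csv"
    rows = ["Word,Conc.M"] + [f"{w},{r}" for w, r in FIXTURE_RATINGS.items()]
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture()
def archive_frame() -> pd.DataFrame:
    """Canonical-column Package table (already read)."""
    return pd.DataFrame(
        {
            "test_id": ["A", "A", "A", "B", "B"],
            "headline": [
                "A tomato story",
                "This secret story",
                "Watch the baby",
                "The big dog",
                "A happy dog",
            ],
            "image_id": ["i1", "i1", "i2", "i3", "i3"],
            "impressions": [1000, 1200, 900, 1100, 1000],
            "clicks": [12, 15, 9, 11, 13],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
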