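import numpy as np
import pytest

from charner.corpus_io import AnnotatedSentence, LabelScheme
from charner.pos_preprocess import ToySegmenter


@pytest.fixture(scope="session")
def scheme() -> LabelScheme:
    return LabelScheme()


@pytest.fixture(scope="session")
def two_cat_scheme() -> LabelScheme:
    return LabelScheme([("AnatomicalPart", "ana"), ("Operation", "ope")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def canonical_segmenter() -> ToySegmenter:
    """Segmenter reproducing the canonical mis-segmentation example:
    the 7-character operation entity is cut into a 4-char noun piece and a
    3-char verb piece, while ordinary words keep their own tags."""
    return ToySegmenter({
        "部分小肠": "n",
        "切除术": "v",
        "行": "v",
        "患者": "n",
        "今日": "t",
        "完成": "v",
    })


@pytest.fixture
def tiny_sentences() -> list[AnnotatedSentence]:
    return [
        AnnotatedSentence(chars=list("abc"), labels=["O", "B_ana", "I_ana"]),
        AnnotatedSentence(chars=list("ba"), labels=["B_dru", "I_dru"]),
        AnnotatedSentence(chars=list("ccc"), labels=["O", "O", "O"]),
    ]
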