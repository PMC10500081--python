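"""Optional transformer backends for classification and tagging.

Both steps of the pipeline are backend contracts: the default backends
(linear classifier, linear-chain perceptron tagger) are self-contained,
while the transformer backends below fine-tune pretrained biomedical
language models and require the optional ``picopipe[transformer]``
dependencies.  They exist as adapters: swapping a backend changes only
predictions, never the report schema or the surrounding pipeline.

Hyperparameter presets
----------------------
* Sentence classification (prompt-style fine-tuning):
  dropout 0.5, batch size 8, learning rate 6e-6, AdamW, weight decay 0.01.
* NER fine-tuning ships two named presets, since both are defensible
  starting points:
  - ``"initial"``: 5 epochs, learning rate 1e-5, batch size 32;
  - ``"tuned"``:  10 epochs, learning rate 5e-5, batch size 8
  (the grid searched was lr in {1e-5, 3e-5, 4e-5, 5e-5, 6e-5}, batch in
  {8, 16, 32}, epochs 5-20).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ClassifierFinetunePreset:
    dropout: float = 0.5
    batch_size: int = 8
    learning_rate: float = 6e-6
    optimizer: str = "AdamW"
    weight_decay: float = 0.01


@dataclass(frozen=True)
class NERFinetunePreset:
    epochs: int
    learning_rate: float
    batch_size: int


NER_PRESETS: dict[str, NERFinetunePreset] = {
    "initial": NERFinetunePreset(epochs=5, learning_rate=1e-5, batch_size=32),
    "tuned": NERFinetunePreset(epochs=10, learning_rate=5e-5, batch_size=8),
}

_INSTALL_HINT = (
    "the transformer backend requires the optional dependencies; "
    "install with `pip install picopipe[transformer]` and use the "
    "default backend otherwise"
)


def _require_transformers():
    try:
        import transformers  # noqa: F401
    except ImportError as exc:
        raise ImportError(_INSTALL_HINT) from exc


def train_transformer_classifier(corpus, seed: int = 0,
                                 preset: ClassifierFinetunePreset | None = None):
    """Fine-tune a masked-LM sentence classifier (optional backend)."""
    _require_transformers()
    raise NotImplementedError(
        "transformer classifier fine-tuning is not bundled; implement a "
        "subclass honoring the ClassifierModel contract"
    )


def train_transformer_tagger(corpus, seed: int = 0, preset: str = "tuned"):
    """Fine-tune a transformer token tagger (optional backend).

    Note: transformer taggers predict token labels independently, so their
    raw output may violate BIO validity; downstream span reconstruction
    applies the conservative-begin repair automatically.
    """
    _require_transformers()
    raise NotImplementedError(
        "transformer NER fine-tuning is not bundled; implement a subclass "
        "honoring the TaggerModel contract"
    )
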