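"""Convenience re-export of the synthetic ground-truth parameter point."""

from .simulate import demo_truth

__all__ = ["demo_truth"]
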