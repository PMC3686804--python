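"""Small shared helpers."""

import numpy as np


def to_plain_python(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: to_plain_python(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_plain_python(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
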