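"""Reading and validating models from COBRA-JSON, and structural diagnostics.

Writes the built-in network to COBRA-JSON (the BIGG dialect), loads it back,
and prints the validation report: whether n > m (the regime where inspection
is guaranteed to find pinned fluxes), fixed reactions, infinite bounds, and
decoupled reactions. SBML L3+FBC files load the same way via load_model().
"""

import tempfile
from pathlib import Path

from fvaprune import example_network, load_model, save_model_json, validate_model

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "example.json"
    save_model_json(example_network(), path)
    model = load_model(path)
    print(f"loaded {model.name!r}: {model.m} metabolites x {model.n} reactions")
    print(validate_model(model).summary())
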