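"""Per-category staff time and the expected minutes per submission.

Composes admin and GP minutes for each of the seven submission outcome
categories from the elementary task timings, then weights them by the
observed category mix. The two totals (admin and GP minutes per
submission) are the inputs every cost figure downstream depends on.
"""

import pandas as pd

from econsult import (
    derive_per_type_resources,
    expected_resource,
    load_default_parameters,
)

params = load_default_parameters()
per_type = derive_per_type_resources(params.timings, params.notes)

rows = [
    {
        "category": cat.label,
        "share": params.mix[cat],
        "admin_min": res.admin_minutes,
        "gp_min": res.gp_minutes,
    }
    for cat, res in per_type.items()
]
print(pd.DataFrame(rows).to_string(index=False))

exp = expected_resource(per_type, params.mix)
admin, gp = exp.rounded(1)
print(
    f"\nExpected time per submission: {admin} admin min, {gp} GP min "
    f"(full precision {exp.admin_minutes_per_econsult:.4f} / "
    f"{exp.gp_minutes_per_econsult:.4f})"
)
print(
    "A submission costs about as much GP time as a 5-minute phone call "
    "and twice the admin time of a booking call."
)
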