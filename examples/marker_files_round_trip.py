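"""Exchange formats: marker CSV in, standard electrode-position files out.

Writes a flickery, alias-labelled motion-capture export (timestamped rows,
vendor label variants), reads it back through the robust CSV reader, runs
localization, and exports the reconstructed montage as .sfp/.elc files that
downstream EEG tools consume.
"""

import tempfile
from pathlib import Path

from sparsecap import (
    REQUIRED_LABELS,
    SyntheticHeadConfig,
    generate_head,
    load_builtin,
    localize,
    read_marker_csv,
    read_positions,
    write_positions,
)

angles = load_builtin("ten_twenty_64")
_, observed = generate_head(SyntheticHeadConfig(marker_noise_sd=0.5, seed=3), angles)
sparse = observed.subset(REQUIRED_LABELS)

work = Path(tempfile.mkdtemp())
raw = work / "motive_export.csv"
with raw.open("w") as fh:
    fh.write("label,x,y,z,t\n")
    for lab, p in sparse.items():
        vendor = {"Nz": "NAS", "LPA": "A1", "RPA": "A2"}.get(lab, lab)
        for k in range(3):  # three camera frames with tiny flicker
            fh.write(f"{vendor},{p[0] + 0.01 * k},{p[1]},{p[2]},{0.01 * k}\n")

markers = read_marker_csv(raw, required=REQUIRED_LABELS)
print(f"read {len(markers)} markers (aliases normalized): {', '.join(markers.labels)}")

result = localize(markers, angles, model_kind="ellipsoid")
montage = result.full_montages["ellipsoid"].points

sfp = write_positions(montage, work / "montage.sfp", "sfp")
elc = write_positions(montage, work / "montage.elc", "elc")
print(f"wrote {sfp.name} and {elc.name} ({len(montage)} electrodes, fiducials first)")

back = read_positions(sfp)
worst = max(abs(back[l] - montage[l]).max() for l in montage.labels)
print(f"sfp round-trip agrees to {worst:.1e} mm (printed precision 1e-4)")
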