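"""Regenerate the packaged template-angle tables from mne's idealized montages.

Build-time utility, not part of the installed package. The committed CSVs under
``src/sparsecap/data/`` are the product; mne is only needed to rerun this script.

Both BioSemi-style montages in mne are ideal spheres whose 10-20 equatorial ring
(T7, T8, FPz, Oz) sits at 92 deg inclination. We scale all inclinations by 90/92
so that ring lies exactly on the equator: with the frame origin defined as the
mean of those four markers, ideal geometry then has a zero z-shift, and template
projection / parameter recovery are exact on noiseless synthetic heads. In the
128-channel table the five channels coinciding with the 10-20 anchor positions
are renamed to their 10-20 names (A1->Cz, A23->Oz, B26->T8, C17->FPz, D23->T7).
"""

from pathlib import Path

import mne
import numpy as np

OUT = Path(__file__).resolve().parent.parent / "src" / "sparsecap" / "data"

ALIAS_128 = {"A1": "Cz", "A23": "Oz", "B26": "T8", "C17": "FPz", "D23": "T7"}
RENAME_64 = {"Fpz": "FPz"}  # canonical capitalization used throughout the package


def angles(montage_name: str) -> list[tuple[str, float, float]]:
    mont = mne.channels.make_standard_montage(montage_name)
    rows = []
    for lab, p in mont.get_positions()["ch_pos"].items():
        r = np.linalg.norm(p)
        theta = np.degrees(np.arccos(p[2] / r)) * (90.0 / 92.0)
        phi = np.degrees(np.arctan2(p[1], p[0]))
        if phi <= -180.0:
            phi += 360.0
        rows.append((lab, round(theta, 4), round(phi, 4)))
    return rows


def write(rows, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("label,theta_deg,phi_deg\n")
        for lab, th, ph in rows:
            fh.write(f"{lab},{th:g},{ph:g}\n")
    print(f"wrote {path} ({len(rows)} rows)")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows64 = [(RENAME_64.get(lab, lab), th, ph) for lab, th, ph in angles("biosemi64")]
    write(rows64, OUT / "ten_twenty_64.csv")
    rows128 = [(ALIAS_128.get(lab, lab), th, ph) for lab, th, ph in angles("biosemi128")]
    write(rows128, OUT / "radial_128.csv")


if __name__ == "__main__":
    main()
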