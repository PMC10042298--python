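"""Regenerate the CSV spectra bundled under src/chromodecomp/data/.

All curves live on the working 450-750 nm grid at 5 nm.  Sources:

* melanin extinction: the standard epidermal-melanosome power-law fit
  mu_a = 6.6e11 * lambda^-3.33 cm^-1, expressed per unit melanosome
  volume fraction.
* hemoglobin extinction: smooth monotone (PCHIP) interpolation through
  anchor values approximating the standard compiled molar extinction
  tables for HbO2 and Hb, converted to whole-blood absorption at
  150 g/L hemoglobin (64500 g/mol), i.e. per unit blood volume fraction.
* illuminant: D65-like daylight approximated by a Planckian radiator at
  6504 K, normalized to 1 at 560 nm.
* CIE 1931 2-degree observer: the Wyman-Sloan multi-lobe Gaussian
  analytic fit.
* camera sensitivities: synthetic DSLR-like Gaussian passbands.
* ColorChecker: a synthetic 24-patch chart (6 neutrals + 18 smooth
  chromatic spectra); a stand-in for a measured chart.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

DATA = Path(__file__).resolve().parents[1] / "src" / "chromodecomp" / "data"
GRID = 450.0 + 5.0 * np.arange(61)  # 450..750 nm


def write_curve(name: str, values: np.ndarray, subdir: str = "") -> None:
    out = DATA / subdir / name
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"wavelength_nm": GRID, "value": np.round(values, 8)}).to_csv(out, index=False)
    print(out)


# --- melanin -----------------------------------------------------------------
mel = 6.6e11 * GRID ** -3.33
write_curve("extinction_melanin.csv", mel)

# --- hemoglobin --------------------------------------------------------------
# anchor molar extinctions (cm^-1 / M), approximate
ANCHORS_OXY = {
    450: 62000, 460: 45000, 470: 33000, 480: 26000, 490: 23000, 500: 21000,
    510: 20200, 520: 24000, 530: 39000, 535: 46000, 542: 53200, 548: 50000,
    555: 37000, 560: 33000, 565: 35000, 569: 44000, 577: 55500, 585: 30000,
    590: 14000, 600: 3200, 610: 1500, 620: 1000, 640: 500, 650: 370,
    680: 290, 700: 290, 720: 330, 750: 420,
}
ANCHORS_DEOXY = {
    450: 55000, 460: 40000, 470: 28000, 480: 23000, 490: 21000, 500: 20500,
    510: 21500, 520: 24500, 530: 30000, 540: 34500, 550: 38500, 556: 39500,
    565: 35000, 570: 32500, 577: 30000, 585: 22000, 590: 17500, 600: 11000,
    610: 8000, 620: 6200, 640: 4400, 650: 3750, 680: 2550, 700: 1850,
    720: 1550, 750: 1400,
}
MOLAR_TO_BLOOD = np.log(10) * 150.0 / 64500.0  # per unit blood volume fraction

for name, anchors in (("oxy", ANCHORS_OXY), ("deoxy", ANCHORS_DEOXY)):
    wl = np.array(sorted(anchors))
    interp = PchipInterpolator(wl, [anchors[w] for w in wl])
    write_curve(f"extinction_hemoglobin_{name}.csv", MOLAR_TO_BLOOD * interp(GRID))

# --- illuminant --------------------------------------------------------------
h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
T = 6504.0
lam = GRID * 1e-9
planck = (2 * h * c**2 / lam**5) / (np.expm1(h * c / (lam * kb * T)))
planck /= np.interp(560.0, GRID, planck)
write_curve("d65_approx_spd.csv", planck)
write_curve("spd.csv", planck, subdir="profile_default")

# --- CIE 1931 2-degree observer (Wyman-Sloan analytic fit) ------------------
def _g(x, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)

xbar = 1.056 * _g(GRID, 599.8, 37.9, 31.0) + 0.362 * _g(GRID, 442.0, 16.0, 26.7) \
    - 0.065 * _g(GRID, 501.1, 20.4, 26.2)
ybar = 0.821 * _g(GRID, 568.8, 46.9, 40.5) + 0.286 * _g(GRID, 530.9, 16.3, 31.1)
zbar = 1.217 * _g(GRID, 437.0, 11.8, 36.0) + 0.681 * _g(GRID, 459.0, 26.0, 13.8)
write_curve("cie1931_xbar.csv", np.clip(xbar, 0, None))
write_curve("cie1931_ybar.csv", np.clip(ybar, 0, None))
write_curve("cie1931_zbar.csv", np.clip(zbar, 0, None))

# --- synthetic DSLR-like sensitivities --------------------------------------
def gauss(mu, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((GRID - mu) / sigma) ** 2)

sens = {
    "r": gauss(598, 38) + gauss(660, 45, 0.55),
    "g": gauss(532, 42) + gauss(565, 35, 0.35),
    "b": gauss(465, 32) + gauss(495, 30, 0.35),
}
for ch, v in sens.items():
    write_curve(f"sensitivity_{ch}.csv", v, subdir="profile_default")

# --- synthetic ColorChecker --------------------------------------------------
rng = np.random.default_rng(20230327)
patches = {}
neutrals = [0.031, 0.090, 0.198, 0.362, 0.591, 0.883]
for i, n in enumerate(neutrals):
    patches[f"patch_{19 + i:02d}"] = np.full(GRID.shape, n)

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))

for i in range(18):
    # smooth chromatic spectra: baseline + sigmoidal red/blue edges + a band
    base = rng.uniform(0.04, 0.15)
    edge_pos = rng.uniform(480, 640)
    edge_amp = rng.uniform(-0.55, 0.65)
    band_mu = rng.uniform(460, 700)
    band_amp = rng.uniform(-0.25, 0.45)
    band_sig = rng.uniform(25, 70)
    r = base + edge_amp * sigmoid((GRID - edge_pos) / rng.uniform(8, 25)) \
        + band_amp * np.exp(-0.5 * ((GRID - band_mu) / band_sig) ** 2)
    patches[f"patch_{i + 1:02d}"] = np.clip(r, 0.02, 0.95)

cols = {"wavelength_nm": GRID}
cols.update({k: np.round(patches[k], 6) for k in sorted(patches)})
pd.DataFrame(cols).to_csv(DATA / "colorchecker_synthetic.csv", index=False)
print(DATA / "colorchecker_synthetic.csv")
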