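{
  "BW": 72.3,
  "VT": 0.95,
  "VLiC": 3.09,
  "VFaC": 19.5,
  "VGuC": 1.5,
  "VStC": 0.22,
  "VSpdC": 60.7,
  "VRpdC": 3.71,
  "VBldC": 5.0,
  "VLymphC": 0.36,
  "QCC": 14.0,
  "QHepartC": 6.0,
  "QFaC": 5.0,
  "QGuC": 14.9,
  "QStC": 1.1,
  "QSpdC": 27.0,
  "QRpdC": 42.0,
  "QLymphC": 0.04,
  "PORALDOSE": 0.555,
  "DRINKTIME": 0.25,
  "FracDOSE": 0.7,
  "k_Ga": 25.1,
  "k_max": 10.2,
  "k_min": 0.005,
  "T12dinch": 30.0,
  "T12dinch_gut": 30.0,
  "T12minch": 30.53,
  "MPY": 34.0,
  "MPY_gut": 3.9,
  "FracMetabOH": 0.25,
  "FracMetabcx": 0.0475,
  "K1_OH": 0.15,
  "K1_cx": 0.15,
  "Rurine": 0.1,
  "Creat": 0.5,
  "FBDINCH": 0.0001249,
  "FBMINCH": 0.0146477,
  "PC_dinch_adipose": 49.77,
  "PC_dinch_liver": 5.89,
  "PC_dinch_gut": 7.4,
  "PC_dinch_stomach": 7.4,
  "PC_dinch_rapid": 3.7,
  "PC_dinch_slow": 3.29,
  "PC_dinch_blood_cells": 3.01,
  "PC_minch_adipose": 29.1,
  "PC_minch_liver": 54.8,
  "PC_minch_gut": 25.2,
  "PC_minch_stomach": 25.2,
  "PC_minch_rapid": 12.2,
  "PC_minch_slow": 7.51,
  "PC_minch_blood_cells": 6.67
}
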