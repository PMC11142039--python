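# Tissue conductivity presets (S/m).
#
# The 7-compartment sets are literature compilations commonly used in EEG
# volume-conduction modeling; the 3-layer sets are their reductions for
# SKIN / SKULL / BRAIN inverse models.  Values are editable; a scaled or
# perturbed copy of a set leaves every interface contrast K unchanged only
# if ALL values are scaled together.
#
# cerebellum note: the VWB compilation gives no cerebellum value; the entry
# below is a 40-60 % weighted average of its GM and WM conductivities,
# used only when the optional extra interior shell is enabled.
ITIS7:
  skin: 0.147
  skull: 0.0179
  csf: 1.880
  gm: 0.419
  wm: 0.348
  cerebellum: 0.577
  ventricles: 1.880
  eyes: 1.880
VWB7:
  skin: 0.430
  skull: 0.010
  csf: 1.790
  gm: 0.330
  wm: 0.140
  cerebellum: 0.216
  ventricles: 1.790
  eyes: 1.790
SimNIBS7:
  skin: 0.465
  skull: 0.010
  csf: 1.654
  gm: 0.275
  wm: 0.126
  cerebellum: 0.126
  ventricles: 1.654
  eyes: 1.654
ITIS3:
  SKIN: 0.147
  SKULL: 0.0179
  BRAIN: 0.375
VWB3:
  SKIN: 0.430
  SKULL: 0.010
  BRAIN: 0.330
SimNIBS3:
  SKIN: 0.465
  SKULL: 0.010
  BRAIN: 0.330
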