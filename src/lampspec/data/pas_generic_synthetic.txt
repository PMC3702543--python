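# SYNTHETIC generic photosynthesis action spectrum (stand-in tabulation).
# Hand-constructed smooth curve reproducing the canonical features of the
# generic, species-averaged photosynthesis action spectrum used in lighting
# standards: a blue absorption peak near 450 nm (chlorophyll a/b Soret bands
# plus carotenoids), a green minimum near 530-550 nm, a dominant red peak at
# 660 nm (chlorophyll red band) and a steep far-red cutoff beyond 700 nm.
# It is NOT a transcription of a standards-body tabulation; absolute
# photosynthesis index values for real lamps depend on the tabulation chosen.
# Columns: wavelength_nm  relative_action
380 0.30
390 0.35
400 0.42
410 0.50
420 0.60
430 0.71
440 0.80
450 0.84
460 0.80
470 0.71
480 0.62
490 0.54
500 0.49
510 0.46
520 0.44
530 0.43
540 0.44
550 0.46
560 0.49
570 0.54
580 0.60
590 0.67
600 0.75
610 0.82
620 0.88
630 0.93
640 0.97
650 0.99
660 1.00
670 0.96
680 0.85
690 0.65
700 0.43
710 0.25
720 0.12
730 0.04
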