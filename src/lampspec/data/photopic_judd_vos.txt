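# Photopic luminous efficiency function V(lambda) with the Judd-Vos correction.
# Below 460 nm the Judd-Vos corrected values are used (they raise the blue lobe
# relative to the 1924 CIE curve); at and above 460 nm the curve coincides with
# the CIE 1931 ybar to the precision tabulated here. 10 nm steps plus the
# 555 nm peak sample.
# Columns: wavelength_nm  sensitivity
380 0.0002
390 0.0008
400 0.0028
410 0.0074
420 0.0175
430 0.0273
440 0.0379
450 0.0468
460 0.0600
470 0.0910
480 0.1390
490 0.2080
500 0.3230
510 0.5030
520 0.7100
530 0.8620
540 0.9540
550 0.9950
555 1.0000
560 0.9950
570 0.9520
580 0.8700
590 0.7570
600 0.6310
610 0.5030
620 0.3810
630 0.2650
640 0.1750
650 0.1070
660 0.0610
670 0.0320
680 0.0170
690 0.0082
700 0.0041
710 0.0021
720 0.0010
730 0.0005
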