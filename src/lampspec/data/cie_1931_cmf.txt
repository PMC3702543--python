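# CIE 1931 2-degree standard colorimetric observer color-matching functions.
# Standard CIE tabulation at 10 nm intervals.
# Columns: wavelength_nm  xbar  ybar  zbar
380 0.0014 0.0000 0.0065
390 0.0042 0.0001 0.0201
400 0.0143 0.0004 0.0679
410 0.0435 0.0012 0.2074
420 0.1344 0.0040 0.6456
430 0.2839 0.0116 1.3856
440 0.3483 0.0230 1.7471
450 0.3362 0.0380 1.7721
460 0.2908 0.0600 1.6692
470 0.1954 0.0910 1.2876
480 0.0956 0.1390 0.8130
490 0.0320 0.2080 0.4652
500 0.0049 0.3230 0.2720
510 0.0093 0.5030 0.1582
520 0.0633 0.7100 0.0782
530 0.1655 0.8620 0.0422
540 0.2904 0.9540 0.0203
550 0.4334 0.9950 0.0087
560 0.5945 0.9950 0.0039
570 0.7621 0.9520 0.0021
580 0.9163 0.8700 0.0017
590 1.0263 0.7570 0.0011
600 1.0622 0.6310 0.0008
610 1.0026 0.5030 0.0003
620 0.8544 0.3810 0.0002
630 0.6424 0.2650 0.0000
640 0.4479 0.1750 0.0000
650 0.2835 0.1070 0.0000
660 0.1649 0.0610 0.0000
670 0.0874 0.0320 0.0000
680 0.0468 0.0170 0.0000
690 0.0227 0.0082 0.0000
700 0.0114 0.0041 0.0000
710 0.0058 0.0021 0.0000
720 0.0029 0.0010 0.0000
730 0.0014 0.0005 0.0000
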