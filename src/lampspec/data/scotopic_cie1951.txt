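# Scotopic luminous efficiency function V'(lambda), CIE 1951.
# Standard tabulation at 10 nm steps plus the 507 nm peak sample.
# Columns: wavelength_nm  sensitivity
380 0.000589
390 0.002209
400 0.00929
410 0.03484
420 0.0966
430 0.1998
440 0.3281
450 0.4550
460 0.5670
470 0.6760
480 0.7930
490 0.9040
500 0.9820
507 1.0000
510 0.9970
520 0.9350
530 0.8110
540 0.6500
550 0.4810
560 0.3288
570 0.2076
580 0.1212
590 0.0655
600 0.03315
610 0.01593
620 0.00737
630 0.003335
640 0.001497
650 0.000677
660 0.0003129
670 0.0001480
680 0.0000715
690 0.00003533
700 0.00001780
710 0.00000914
720 0.00000478
730 0.00000255
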