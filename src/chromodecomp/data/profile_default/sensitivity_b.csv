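wavelength_nm,value
450.0,1.00958498
455.0,1.0962341
460.0,1.16508464
465.0,1.21228573
470.0,1.23519407
475.0,1.23260289
480.0,1.20483054
485.0,1.15366338
490.0,1.0821663
495.0,0.99438872
500.0,0.89500338
505.0,0.78891918
510.0,0.6809081
515.0,0.57528075
520.0,0.47563693
525.0,0.38470735
530.0,0.30429114
535.0,0.23528306
540.0,0.1777751
545.0,0.13121021
550.0,0.09456318
555.0,0.06652452
560.0,0.04566695
565.0,0.03058066
570.0,0.01997056
575.0,0.01271499
580.0,0.00789074
585.0,0.00477198
590.0,0.00281171
595.0,0.00161382
600.0,0.00090216
605.0,0.00049112
610.0,0.00026033
615.0,0.00013434
620.0,6.749e-05
625.0,3.3e-05
630.0,1.571e-05
635.0,7.28e-06
640.0,3.28e-06
645.0,1.44e-06
650.0,6.1e-07
655.0,2.6e-07
660.0,1e-07
665.0,4e-08
670.0,2e-08
675.0,1e-08
680.0,0.0
685.0,0.0
690.0,0.0
695.0,0.0
700.0,0.0
705.0,0.0
710.0,0.0
715.0,0.0
720.0,0.0
725.0,0.0
730.0,0.0
735.0,0.0
740.0,0.0
745.0,0.0
750.0,0.0
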