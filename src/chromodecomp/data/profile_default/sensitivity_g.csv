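wavelength_nm,value
450.0,0.15027344
455.0,0.18877764
460.0,0.23395445
465.0,0.28606855
470.0,0.34515705
475.0,0.41098354
480.0,0.48300197
485.0,0.56033428
490.0,0.64176477
495.0,0.72575354
500.0,0.81046934
505.0,0.89384157
510.0,0.97362946
515.0,1.04750598
520.0,1.1131531
525.0,1.16836466
530.0,1.21115259
535.0,1.23985149
540.0,1.25321606
545.0,1.25050476
550.0,1.231543
555.0,1.19675868
560.0,1.14718413
565.0,1.08442054
570.0,1.01056366
575.0,0.92809407
580.0,0.83973905
585.0,0.74831688
590.0,0.65657722
595.0,0.56705173
600.0,0.48192841
605.0,0.40295985
610.0,0.33141164
615.0,0.26805223
620.0,0.21318063
625.0,0.16668481
630.0,0.12812092
635.0,0.09680287
640.0,0.07189216
645.0,0.05247998
650.0,0.03765571
655.0,0.02655903
660.0,0.0184149
665.0,0.01255297
670.0,0.00841396
675.0,0.00554625
680.0,0.00359605
685.0,0.00229388
690.0,0.00143993
695.0,0.0008897
700.0,0.00054126
705.0,0.00032431
710.0,0.00019144
715.0,0.00011137
720.0,6.387e-05
725.0,3.612e-05
730.0,2.015e-05
735.0,1.109e-05
740.0,6.03e-06
745.0,3.23e-06
750.0,1.71e-06
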