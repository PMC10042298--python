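wavelength_nm,value
450.0,0.34371675
455.0,0.31719319
460.0,0.28104655
465.0,0.23810018
470.0,0.19154448
475.0,0.14464986
480.0,0.10055437
485.0,0.06211179
490.0,0.03176275
495.0,0.01140213
500.0,0.00225333
505.0,0.00433486
510.0,0.01654377
515.0,0.03856369
520.0,0.07004303
525.0,0.11061554
530.0,0.1599135
535.0,0.21753529
540.0,0.28297244
545.0,0.35550862
550.0,0.43410955
555.0,0.51732716
560.0,0.60324077
565.0,0.68945432
570.0,0.77315988
575.0,0.85126816
580.0,0.92059604
585.0,0.97809214
590.0,1.02107547
595.0,1.04745918
600.0,1.0559257
605.0,1.04122249
610.0,1.00034562
615.0,0.93638797
620.0,0.85400855
625.0,0.75887452
630.0,0.65702126
635.0,0.55423091
640.0,0.45551639
645.0,0.36477012
650.0,0.28460106
655.0,0.21634944
660.0,0.16024225
665.0,0.11563794
670.0,0.08130657
675.0,0.05569971
680.0,0.03717768
685.0,0.02417763
690.0,0.01531959
695.0,0.00945763
700.0,0.00568879
705.0,0.00333395
710.0,0.00190371
715.0,0.00105912
720.0,0.0005741
725.0,0.00030321
730.0,0.00015602
735.0,7.822e-05
740.0,3.821e-05
745.0,1.819e-05
750.0,8.43e-06
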