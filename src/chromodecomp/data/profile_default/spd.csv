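wavelength_nm,value
450.0,1.1227123
455.0,1.12179349
460.0,1.12025099
465.0,1.11811517
470.0,1.11541583
475.0,1.11218211
480.0,1.1084425
485.0,1.10422472
490.0,1.09955576
495.0,1.09446182
500.0,1.0889683
505.0,1.08309977
510.0,1.07687999
515.0,1.07033187
520.0,1.06347751
525.0,1.05633817
530.0,1.0489343
535.0,1.04128553
540.0,1.03341068
545.0,1.02532781
550.0,1.01705418
555.0,1.00860632
560.0,1.0
565.0,0.99125028
570.0,0.98237151
575.0,0.97337738
580.0,0.96428091
585.0,0.95509446
590.0,0.9458298
595.0,0.93649809
600.0,0.92710992
605.0,0.9176753
610.0,0.90820374
615.0,0.8987042
620.0,0.88918517
625.0,0.87965465
630.0,0.87012019
635.0,0.86058889
640.0,0.85106745
645.0,0.84156214
650.0,0.83207888
655.0,0.8226232
660.0,0.81320027
665.0,0.80381495
670.0,0.79447176
675.0,0.78517493
680.0,0.77592838
685.0,0.76673578
690.0,0.75760051
695.0,0.74852571
700.0,0.73951429
705.0,0.73056891
710.0,0.72169204
715.0,0.71288592
720.0,0.70415263
725.0,0.69549403
730.0,0.68691183
735.0,0.67840756
740.0,0.66998261
745.0,0.66163821
750.0,0.65337545
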