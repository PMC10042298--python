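wavelength_nm,value
450.0,0.03319479
455.0,0.04324359
460.0,0.05570773
465.0,0.07098655
470.0,0.08953218
475.0,0.11190913
480.0,0.13891934
485.0,0.1717988
490.0,0.21242353
495.0,0.26334354
500.0,0.32735772
505.0,0.40639756
510.0,0.49983757
515.0,0.6029321
520.0,0.70649772
525.0,0.79869229
530.0,0.86864005
535.0,0.91675412
540.0,0.95393878
545.0,0.9798778
550.0,0.99446404
555.0,0.99803862
560.0,0.99128193
565.0,0.97509469
570.0,0.95039783
575.0,0.91608581
580.0,0.87244574
585.0,0.82086846
590.0,0.76289601
595.0,0.70018011
600.0,0.63443207
605.0,0.56736327
610.0,0.50061884
615.0,0.43571016
620.0,0.37395307
625.0,0.31641876
630.0,0.26390244
635.0,0.21691256
640.0,0.17568031
645.0,0.14018691
650.0,0.1102039
655.0,0.08534138
660.0,0.06509847
665.0,0.04891159
670.0,0.03619665
675.0,0.02638339
680.0,0.01894047
685.0,0.01339193
690.0,0.00932577
695.0,0.00639606
700.0,0.0043204
705.0,0.00287421
710.0,0.0018832
715.0,0.00121522
720.0,0.00077232
725.0,0.00048341
730.0,0.000298
735.0,0.00018093
740.0,0.00010818
745.0,6.371e-05
750.0,3.695e-05
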